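"""Construction of the CRP-weighted cis-IL6R instrumental variable.

The instrument proxies pharmacological IL-6R blockade: variants near *IL6R*
that raise circulating IL-6R (impaired classical signalling) and lower CRP
(the downstream readout of IL-6 activity).  Selection pipeline:

1. ``select_cis`` — SNPs within a window (default 300 kb) of the gene.
2. ``filter_significant`` — genome-wide significant for IL-6R level
   (p < 5e-8, strict) in the selection GWAS.
3. ``concordance_filter`` — the IL6R-raising allele must *lower* CRP; SNPs
   whose two effects share a sign are removed and the survivors re-oriented
   so the IL6R-raising allele is the effect allele.
4. ``greedy_clump`` — approximate independence at a pairwise r² threshold
   (default 0.1; 0.01 in the stricter sensitivity analysis).
5. F-statistic filter — (beta/se)² > 10 in the selection GWAS, the
   conventional weak-instrument guard.

The surviving SNPs are weighted by their CRP effect, then the exposure sign
is flipped globally so one exposure unit means one unit *decrease* in
natural-log CRP: downstream odds ratios below 1 read as protection under
IL-6 inhibition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyResultError, HarmonisationError
from .harmonise import harmonise_frames
from .ld import LDMatrix
from .sumstats import SumStats

logger = logging.getLogger(__name__)


@dataclass
class GeneRegion:
    """A gene's span plus the cis window on either side (closed interval)."""

    chrom: str
    start: int
    end: int
    window: int = 300_000
    build: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ConfigurationError("GeneRegion requires start < end")
        if self.window < 0:
            raise ConfigurationError("GeneRegion window must be >= 0")

    @property
    def lo(self) -> int:
        return self.start - self.window

    @property
    def hi(self) -> int:
        return self.end + self.window


@dataclass
class Instrument:
    """The selected, CRP-weighted SNP set.

    ``beta_exposure`` is the per-allele *decrease* in natural-log CRP (always
    positive after orientation), ``f_stat`` the (beta/se)² of the selection
    GWAS.  Selection-GWAS effects are retained as ``beta_selection`` /
    ``se_selection`` / ``pval_selection`` for audit.
    """

    df: pd.DataFrame
    exposure_label: str = "decrease in log CRP (IL-6R proxied)"
    audit: dict = field(default_factory=dict)

    REQUIRED = ["snp_id", "effect_allele", "other_allele",
                "beta_exposure", "se_exposure", "pval_exposure", "f_stat", "eaf"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"Instrument frame missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df["snp_id"])


def select_cis(table: SumStats, region: GeneRegion) -> SumStats:
    """Keep SNPs on the region's chromosome within [start-window, end+window]."""
    df = table.df
    keep = (
        (df["chrom"].astype(str) == str(region.chrom))
        & (df["pos"] >= region.lo)
        & (df["pos"] <= region.hi)
    )
    if not keep.any():
        raise EmptyResultError(
            "select_cis",
            f"no SNPs on chrom {region.chrom} in [{region.lo}, {region.hi}]",
        )
    return replace(table, df=df.loc[keep].reset_index(drop=True))


def filter_significant(table: SumStats, p_threshold: float = 5e-8) -> SumStats:
    """Keep SNPs with pval strictly below the threshold."""
    if not 0 < p_threshold < 1:
        raise ConfigurationError("p_threshold must lie in (0, 1)")
    keep = table.df["pval"] < p_threshold
    return replace(table, df=table.df.loc[keep].reset_index(drop=True))


def f_statistic(beta, se):
    """Instrument-strength F-statistic, (beta/se)²."""
    return (np.asarray(beta, dtype=float) / np.asarray(se, dtype=float)) ** 2


def concordance_filter(il6r: pd.DataFrame, crp: pd.DataFrame) -> pd.DataFrame:
    """Keep SNPs whose IL6R and CRP effects point in opposite directions.

    Inputs are frames already aligned to a common effect-allele orientation
    (same ``effect_allele``/``other_allele`` per snp_id); an allele mismatch
    is fatal.  Survivors are re-oriented so the IL6R-*raising* allele is the
    effect allele, i.e. ``beta_il6r > 0`` and ``beta_crp < 0`` on every row
    of the returned paired frame.
    """
    merged = il6r.merge(crp, on="snp_id", suffixes=("_il6r", "_crp"))
    mism = (
        (merged["effect_allele_il6r"] != merged["effect_allele_crp"])
        | (merged["other_allele_il6r"] != merged["other_allele_crp"])
    )
    if mism.any():
        bad = list(merged.loc[mism, "snp_id"].head(5))
        raise HarmonisationError(
            f"concordance_filter requires pre-harmonised inputs; allele "
            f"mismatch at e.g. {bad}"
        )
    keep = merged["beta_il6r"] * merged["beta_crp"] < 0
    out = merged.loc[keep].copy()
    flip = out["beta_il6r"] < 0
    for col in ("beta_il6r", "beta_crp"):
        out.loc[flip, col] = -out.loc[flip, col]
    ea = out["effect_allele_il6r"].where(~flip, out["other_allele_il6r"])
    oa = out["other_allele_il6r"].where(~flip, out["effect_allele_il6r"])
    out["effect_allele"], out["other_allele"] = ea, oa
    for col in ("eaf_il6r", "eaf_crp"):
        if col in out.columns:
            out.loc[flip, col] = 1.0 - out.loc[flip, col]
    return out.drop(columns=["effect_allele_il6r", "other_allele_il6r",
                             "effect_allele_crp", "other_allele_crp"]).reset_index(drop=True)


def _clump_frame(df: pd.DataFrame, ld: LDMatrix, r2_threshold: float) -> pd.DataFrame:
    """Greedy clumping on any frame with snp_id/pval (pos, if present, breaks
    p-value ties; snp_id breaks the rest). Returns index SNPs in selection order."""
    missing = [s for s in df["snp_id"] if s not in set(ld.snp_ids)]
    if missing:
        raise ConfigurationError(f"SNPs absent from LD matrix: {missing[:10]}")
    sub = ld.subset(list(df["snp_id"]))
    r2 = sub.r2
    pos = df["pos"] if "pos" in df.columns else pd.Series(0, index=df.index)
    order = np.lexsort((
        df["snp_id"].to_numpy(),
        pos.fillna(0).to_numpy(),
        df["pval"].to_numpy(),
    ))
    remaining = list(order)
    picked: list[int] = []
    while remaining:
        idx = remaining.pop(0)
        picked.append(idx)
        remaining = [j for j in remaining if r2[idx, j] < r2_threshold]
    return df.iloc[picked].reset_index(drop=True)


def greedy_clump(table: SumStats, ld: LDMatrix, r2_threshold: float = 0.1) -> SumStats:
    """Iterative index-SNP selection: repeatedly take the remaining SNP with
    the lowest p-value and discard everything correlated with it at
    r² >= ``r2_threshold``.  Retained SNPs are returned in selection order
    and are pairwise independent at the threshold by construction."""
    return replace(table, df=_clump_frame(table.df, ld, r2_threshold))


def build_instrument(
    il6r: SumStats,
    crp: SumStats,
    region: GeneRegion,
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.1,
    f_threshold: float = 10.0,
    palindrome_eaf_limit: float = 0.42,
) -> Instrument:
    """Run the full selection pipeline and weight the survivors by CRP.

    Stage order follows the selection narrative: cis window → selection-GWAS
    significance → CRP-direction concordance → LD clumping (on selection
    p-values) → F > ``f_threshold``.  The returned instrument's
    ``beta_exposure`` is the *negated* CRP beta of the IL6R-raising allele —
    positive by construction — so that effects downstream are per unit
    decrease in log CRP.

    Raises :class:`EmptyResultError` naming the first stage that empties the
    candidate set.
    """
    audit: dict[str, int] = {"input": len(il6r)}

    cis = select_cis(il6r, region)
    audit["cis_window"] = len(cis)

    sig = filter_significant(cis, p_threshold)
    audit["significant"] = len(sig)
    if len(sig) == 0:
        raise EmptyResultError("filter_significant", f"p_threshold={p_threshold}")

    # Align the CRP table onto the selection table's orientation first.
    aligned = harmonise_frames(sig.df, crp.df, palindrome_eaf_limit)
    ok = aligned["status"].isin(["aligned", "swapped", "strand_flipped"])
    audit["crp_aligned"] = int(ok.sum())
    if not ok.any():
        raise EmptyResultError("crp_alignment", f"statuses: "
                               f"{aligned['status'].value_counts().to_dict()}")
    il6r_frame = aligned.loc[ok, ["snp_id", "chrom", "pos", "effect_allele",
                                  "other_allele", "eaf", "beta", "se", "pval"]]
    crp_frame = pd.DataFrame({
        "snp_id": aligned.loc[ok, "snp_id"],
        "effect_allele": aligned.loc[ok, "effect_allele"],
        "other_allele": aligned.loc[ok, "other_allele"],
        "eaf": aligned.loc[ok, "eaf_y"],
        "beta": aligned.loc[ok, "beta_y"],
        "se": aligned.loc[ok, "se_y"],
        "pval": aligned.loc[ok, "pval_y"],
    })

    paired = concordance_filter(il6r_frame, crp_frame)
    audit["concordant"] = len(paired)
    if len(paired) == 0:
        raise EmptyResultError("concordance_filter", "no sign-discordant SNPs")

    clumped = _clump_frame(paired.rename(columns={"pval_il6r": "pval"}), ld,
                           r2_threshold)
    audit["clumped"] = len(clumped)

    fstat = f_statistic(clumped["beta_il6r"], clumped["se_il6r"])
    strong = clumped.loc[fstat > f_threshold].copy()
    strong["f_stat"] = fstat[fstat > f_threshold]
    audit["f_filtered"] = len(strong)
    if len(strong) == 0:
        raise EmptyResultError("f_filter", f"f_threshold={f_threshold}")

    logger.info("build_instrument: %s", audit)
    df = pd.DataFrame({
        "snp_id": strong["snp_id"],
        "chrom": strong.get("chrom"),
        "pos": strong.get("pos"),
        "effect_allele": strong["effect_allele"],
        "other_allele": strong["other_allele"],
        # global sign flip: report per DECREASE in log CRP
        "beta_exposure": -strong["beta_crp"],
        "se_exposure": strong["se_crp"],
        "pval_exposure": strong["pval_crp"],
        "f_stat": strong["f_stat"],
        "eaf": strong["eaf_il6r"],
        "beta_selection": strong["beta_il6r"],
        "se_selection": strong["se_il6r"],
        "pval_selection": strong["pval"],
    })
    return Instrument(df=df, audit=audit)


def restrict_dual_pqtl(
    instr: Instrument, crp: SumStats, p_threshold: float = 5e-8
) -> Instrument:
    """Sensitivity restriction: keep only SNPs that are genome-wide
    significant pQTLs for CRP as well as for IL-6R (strict inequality)."""
    pvals = crp.df.set_index("snp_id")["pval"]
    missing = [s for s in instr.snp_ids if s not in pvals.index]
    if missing:
        raise ConfigurationError(f"instrument SNPs absent from CRP table: {missing[:10]}")
    keep = instr.df["snp_id"].map(pvals) < p_threshold
    audit = dict(instr.audit, dual_pqtl=int(keep.sum()))
    return Instrument(df=instr.df.loc[keep].reset_index(drop=True),
                      exposure_label=instr.exposure_label, audit=audit)
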