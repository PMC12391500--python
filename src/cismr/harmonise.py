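"""Allele harmonisation between two summary-statistics sources.

Two GWAS report the same SNP with arbitrary choices of effect allele and,
occasionally, opposite strands.  Before any exposure/outcome effect pair can
enter an MR estimator, the outcome record must be re-expressed per copy of
the *exposure's* effect allele.  Four situations arise:

``aligned``
    Identical allele pair, identical orientation — nothing to do.
``swapped``
    Same pair, effect/other reversed — negate the outcome beta and flip its
    allele frequency.
``strand_flipped``
    The outcome alleles are the base-complement of the exposure's (the two
    GWAS read opposite strands) — complement, then align as above.
``dropped_palindromic`` / ``dropped_mismatch``
    A/T and C/G SNPs are their own strand complement, so letters alone cannot
    orient them; they are resolved by allele-frequency agreement when both
    frequencies are far from 0.5, otherwise dropped.  Irreconcilable allele
    pairs are dropped outright.

The audit trail (one status per input SNP) is a mandatory output: drop counts
are part of the reproducibility surface of an MR analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyResultError, HarmonisationError

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Allele frequencies inside [limit, 1-limit] are too close to 0.5 to orient
#: a palindromic SNP; 0.42 is common practice in two-sample MR software.
DEFAULT_PALINDROME_EAF_LIMIT = 0.42

STATUSES = (
    "aligned",
    "swapped",
    "strand_flipped",
    "dropped_palindromic",
    "dropped_mismatch",
    "missing_outcome",
)


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G pairs read the same on both strands."""
    return COMPLEMENT.get(a1) == a2


def resolve_alleles(
    ea_x: str,
    oa_x: str,
    ea_y: str,
    oa_y: str,
    eaf_x: float,
    eaf_y: float,
    palindrome_eaf_limit: float = DEFAULT_PALINDROME_EAF_LIMIT,
) -> tuple[str, bool]:
    """Orient record *y* onto *x*'s effect allele.

    Returns ``(status, flip)`` where ``flip`` means: negate y's beta and
    replace its allele frequency by ``1 - eaf``.  For dropped statuses the
    flip flag is meaningless and returned as ``False``.

    Palindromic SNPs are resolved by frequency agreement alone: the four
    orientation hypotheses (as-written / swapped, same / opposite strand)
    collapse to two observationally distinct ones, distinguished by whether
    the two reported frequencies sit on the same side of 0.5.  Both
    frequencies must lie outside ``[limit, 1-limit]`` for the call to be made.
    """
    pair_x = (ea_x, oa_x)
    if is_palindromic(ea_x, oa_x):
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return "dropped_palindromic", False
        if eaf_x is None or eaf_y is None or np.isnan(eaf_x) or np.isnan(eaf_y):
            return "dropped_palindromic", False
        lo, hi = palindrome_eaf_limit, 1.0 - palindrome_eaf_limit
        if lo <= eaf_x <= hi or lo <= eaf_y <= hi:
            return "dropped_palindromic", False
        # Letter-level alignment first, then a frequency check that detects
        # a hidden strand flip (which, for a palindrome, acts as a swap).
        letter_flip = (ea_y, oa_y) != pair_x
        eaf_aligned = 1.0 - eaf_y if letter_flip else eaf_y
        freq_flip = (eaf_x - 0.5) * (eaf_aligned - 0.5) < 0
        flip = letter_flip != freq_flip
        if freq_flip:
            return "strand_flipped", flip
        return ("swapped" if letter_flip else "aligned"), flip

    if (ea_y, oa_y) == pair_x:
        return "aligned", False
    if (oa_y, ea_y) == pair_x:
        return "swapped", True
    cy = (COMPLEMENT.get(ea_y, "?"), COMPLEMENT.get(oa_y, "?"))
    if cy == pair_x:
        return "strand_flipped", False
    if cy[::-1] == pair_x:
        return "strand_flipped", True
    return "dropped_mismatch", False


@dataclass
class HarmonisedSet:
    """Exposure/outcome effect pairs on a common effect-allele orientation.

    ``variants`` has one row per retained SNP with columns
    ``snp_id, effect_allele, other_allele, bx, bx_se, by, by_se,
    eaf_exposure, eaf_outcome, status`` — bx is the exposure beta (decrease
    in log CRP per allele in the primary analysis), by the outcome log-odds.
    ``audit`` counts every input SNP by final status (retained or dropped).
    """

    variants: pd.DataFrame
    audit: dict = field(default_factory=dict)
    audit_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.variants):
            if (self.variants["bx_se"] <= 0).any() or (self.variants["by_se"] <= 0).any():
                raise HarmonisationError("retained variants must have positive SEs")

    def __len__(self) -> int:
        return len(self.variants)

    def write_audit(self, path) -> None:
        """Emit the harmonisation audit TSV: snp_id, status, action."""
        if self.audit_table is not None:
            self.audit_table.to_csv(path, sep="\t", index=False)


_ACTION = {
    "aligned": "none",
    "swapped": "beta negated; eaf complemented",
    "strand_flipped": "alleles complemented",
    "dropped_palindromic": "dropped (ambiguous palindrome)",
    "dropped_mismatch": "dropped (irreconcilable alleles)",
    "missing_outcome": "dropped (absent from outcome GWAS)",
}


def harmonise_frames(
    x: pd.DataFrame,
    y: pd.DataFrame,
    palindrome_eaf_limit: float = DEFAULT_PALINDROME_EAF_LIMIT,
) -> pd.DataFrame:
    """Core harmonisation on two frames sharing canonical allele columns.

    ``x`` supplies the reference orientation.  Returns one row per SNP of
    ``x`` (in x's order) with x's columns, y's ``beta/se/pval/eaf/n``
    re-oriented and suffixed ``_y``, and a ``status`` column.  Dropped and
    missing SNPs are included with NaN y-fields so callers can build a full
    audit; filter on ``status`` to get the retained set.
    """
    ymap = y.set_index("snp_id")
    rows = []
    for rec in x.itertuples(index=False):
        d = rec._asdict()
        if rec.snp_id not in ymap.index:
            d.update(status="missing_outcome", beta_y=np.nan, se_y=np.nan,
                     pval_y=np.nan, eaf_y=np.nan, n_y=np.nan)
            rows.append(d)
            continue
        yr = ymap.loc[rec.snp_id]
        status, flip = resolve_alleles(
            rec.effect_allele, rec.other_allele,
            str(yr["effect_allele"]), str(yr["other_allele"]),
            rec.eaf, yr["eaf"], palindrome_eaf_limit,
        )
        if status.startswith("dropped"):
            d.update(status=status, beta_y=np.nan, se_y=np.nan,
                     pval_y=np.nan, eaf_y=np.nan, n_y=np.nan)
        else:
            sign = -1.0 if flip else 1.0
            eaf_y = yr["eaf"]
            if flip and not pd.isna(eaf_y):
                eaf_y = 1.0 - eaf_y
            d.update(status=status, beta_y=sign * yr["beta"], se_y=yr["se"],
                     pval_y=yr["pval"], eaf_y=eaf_y, n_y=yr["n"])
        rows.append(d)
    return pd.DataFrame(rows)


def harmonise(
    instrument,
    outcome,
    palindrome_eaf_limit: float = DEFAULT_PALINDROME_EAF_LIMIT,
) -> HarmonisedSet:
    """Harmonise an instrument against a case-control outcome GWAS.

    The instrument fixes the orientation (its effect allele is, by
    construction, the allele that lowers CRP via higher IL-6R); the outcome's
    log-odds are re-expressed per copy of that allele.

    Raises
    ------
    ConfigurationError
        The outcome table is not on the log-odds scale.
    EmptyResultError
        No instrument SNP survives harmonisation.
    """
    if outcome.trait_scale != "log_odds":
        raise ConfigurationError(
            f"outcome must be on the log_odds scale, got {outcome.trait_scale!r}"
        )
    x = instrument.df.rename(columns={
        "beta_exposure": "beta", "se_exposure": "se", "pval_exposure": "pval",
    })
    if "n" not in x.columns:
        x["n"] = np.nan
    merged = harmonise_frames(x, outcome.df, palindrome_eaf_limit)

    audit_table = pd.DataFrame({
        "snp_id": merged["snp_id"],
        "status": merged["status"],
        "action": merged["status"].map(_ACTION),
    })
    audit = merged["status"].value_counts().to_dict()

    keep = merged["status"].isin(["aligned", "swapped", "strand_flipped"])
    if not keep.any():
        raise EmptyResultError("harmonise", f"statuses: {audit}")
    kept = merged.loc[keep]
    variants = pd.DataFrame({
        "snp_id": kept["snp_id"],
        "effect_allele": kept["effect_allele"],
        "other_allele": kept["other_allele"],
        "bx": kept["beta"].astype(float),
        "bx_se": kept["se"].astype(float),
        "by": kept["beta_y"].astype(float),
        "by_se": kept["se_y"].astype(float),
        "eaf_exposure": kept["eaf"].astype(float),
        "eaf_outcome": kept["eaf_y"].astype(float),
        "status": kept["status"],
    }).reset_index(drop=True)
    return HarmonisedSet(variants=variants, audit=audit, audit_table=audit_table)
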