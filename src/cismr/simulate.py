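"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the geometry of the study data: a cis pQTL GWAS for
IL-6R (quantitative, trait-SD scale), a CRP GWAS used for weighting
(quantitative, natural-log scale), and a rare-disease case-control outcome
GWAS (log-odds scale), all over one SNP panel with block LD.

Summary statistics are simulated directly — no individual-level genotypes.
True per-SNP effects are drawn once; each GWAS reports truth plus Gaussian
estimation noise with the standard large-sample standard errors:

* quantitative trait: se = sd_trait / sqrt(2 n p (1-p)),
* case-control log-OR: se = sqrt((1/ncase + 1/ncontrol) / (2 p (1-p))).

By default the estimation noise is independent across SNPs: the LD matrix
is consumed by clumping, not by the noise model (``ld_noise=True`` draws
correlated noise instead).  Every random draw flows from one generator
seeded by ``SimConfig.seed``, so outputs are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .instrument import GeneRegion
from .ld import LDMatrix, write_ld_matrix
from .sumstats import CANONICAL_COLUMNS, SumStats, write_sumstats

#: IL6R locus (GRCh37) used to position synthetic SNPs; analysis code never
#: hardcodes this — it flows through GeneRegion config.
IL6R_REGION = GeneRegion(chrom="1", start=154_377_669, end=154_441_926,
                         window=300_000, build="GRCh37")

_PVAL_FLOOR = 1e-300  # keep p-values inside (0, 1] under extreme z


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic two-sample design.

    The defaults mirror the analysed study: a 44-SNP instrument, a CRP
    (weighting) GWAS of 575,000, an IL-6R selection GWAS of 54,219, and a
    pyothorax outcome GWAS of 1,601 cases / 830,709 controls with a true
    causal log-OR of -1.47 per unit decrease in log CRP and no pleiotropy.
    ``exposure_var_explained`` is the total CRP variance explained by the
    panel (2%, a realistic figure for a strong cis instrument).
    """

    m: int = 44
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_sizes: list[int] | None = None
    ld_rho: float = 0.0
    n_exposure: int = 575_000
    n_selection: int = 54_219
    n_outcome_case: int = 1_601
    n_outcome_control: int = 830_709
    true_effect: float = -1.47
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    exposure_var_explained: float = 0.02
    selection_effect_scale: float = 3.0
    noise_scale: float = 1.0
    ld_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not abs(self.ld_rho) < 1:
            raise ConfigurationError("|ld_rho| must be < 1")
        if not 0 < self.exposure_var_explained < 1:
            raise ConfigurationError("exposure_var_explained must be in (0, 1)")
        if self.ld_block_sizes is None:
            self.ld_block_sizes = [self.m]
        if sum(self.ld_block_sizes) != self.m:
            raise ConfigurationError("ld_block_sizes must sum to m")


@dataclass
class SimTruth:
    """Ground truth behind one simulated dataset (bit-reproducible from the
    config's seed)."""

    beta_exposure_true: np.ndarray  # per-allele DECREASE in log CRP
    beta_direct_true: np.ndarray    # direct (pleiotropic) SNP->outcome log-OR
    true_effect: float
    ld: LDMatrix
    maf: np.ndarray
    config: SimConfig


def simulate_ld(cfg: SimConfig) -> LDMatrix:
    """Block-diagonal correlation; within-block AR(1) with parameter ld_rho,
    so r(i, j) = rho^|i-j| inside a block and 0 across blocks."""
    m = cfg.m
    r = np.eye(m)
    off = 0
    for size in cfg.ld_block_sizes:
        idx = np.arange(size)
        block = cfg.ld_rho ** np.abs(idx[:, None] - idx[None, :])
        r[off:off + size, off:off + size] = block
        off += size
    if np.linalg.eigvalsh(r).min() <= 0:
        raise ConfigurationError("requested LD structure is not positive definite")
    ids = [f"rs{900000 + i}" for i in range(m)]
    return LDMatrix(ids, r)


_NONREF = {"A": ["C", "G"], "C": ["A", "T"], "G": ["A", "T"], "T": ["C", "G"]}


def _draw_alleles(rng: np.random.Generator, m: int) -> tuple[list[str], list[str]]:
    """Random non-palindromic allele pairs (palindrome handling is exercised
    by dedicated harmoniser tests, not by default fixtures)."""
    eas, oas = [], []
    for _ in range(m):
        ea = "ACGT"[rng.integers(4)]
        oa = _NONREF[ea][rng.integers(2)]
        eas.append(ea)
        oas.append(oa)
    return eas, oas


def _table(ids, chrom, pos, ea, oa, eaf, beta, se, n, label, scale) -> SumStats:
    z = np.abs(beta / se)
    pval = np.clip(2.0 * stats.norm.sf(z), _PVAL_FLOOR, 1.0)
    df = pd.DataFrame({
        "snp_id": ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pval": pval, "n": n,
    })[CANONICAL_COLUMNS]
    return SumStats(df, trait_label=label, trait_scale=scale)


def simulate_two_sample(cfg: SimConfig) -> dict:
    """Generate the three summary-statistics tables plus ground truth.

    Returns ``{"exposure": il6r pQTL table, "crp": CRP table,
    "outcome": case-control table, "ld": LDMatrix, "truth": SimTruth}``.

    Effect-size model: per-SNP magnitudes are uniform on [0.5, 1.5] before a
    global rescale to the requested ``exposure_var_explained`` (bounded away
    from zero, so every panel SNP is a genuine instrument); each SNP's
    written effect allele is the CRP-lowering allele with probability 1/2.
    The IL-6R effect of the CRP-lowering allele is positive (receptor up,
    signalling down) with magnitude ``selection_effect_scale`` times the CRP
    effect.  True outcome log-OR per allele = true_effect x (per-allele
    decrease in log CRP) + a direct pleiotropic effect drawn from
    N(pleiotropy_mean, pleiotropy_sd), attached to the CRP-lowering allele
    so that a nonzero mean produces directional (not balanced) pleiotropy.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.m
    ld = simulate_ld(cfg)
    ids = ld.snp_ids

    maf = rng.uniform(*cfg.maf_range, size=m)
    het = 2 * maf * (1 - maf)

    # magnitude of the per-allele CRP effect, scaled to the target r2
    raw = rng.uniform(0.5, 1.5, size=m)
    scale = np.sqrt(cfg.exposure_var_explained / np.sum(het * raw**2))
    mag = raw * scale
    orient = rng.choice([-1.0, 1.0], size=m)  # which written allele lowers CRP

    beta_crp_true = -orient * mag                      # log CRP per effect allele
    x_true = orient * mag                              # DECREASE in log CRP
    beta_sel_true = orient * mag * cfg.selection_effect_scale
    # direct effects are defined per copy of the CRP-lowering (exposure-
    # raising) allele, so a nonzero mean is genuinely directional pleiotropy
    alpha = (rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=m)
             if cfg.pleiotropy_sd > 0 or cfg.pleiotropy_mean != 0 else np.zeros(m))
    beta_out_true = cfg.true_effect * x_true + orient * alpha

    se_crp = 1.0 / np.sqrt(2 * cfg.n_exposure * maf * (1 - maf))
    se_sel = 1.0 / np.sqrt(2 * cfg.n_selection * maf * (1 - maf))
    se_out = np.sqrt((1.0 / cfg.n_outcome_case + 1.0 / cfg.n_outcome_control)
                     / (2 * maf * (1 - maf)))

    if cfg.ld_noise:
        chol = np.linalg.cholesky(ld.r)
        draw = lambda: chol @ rng.standard_normal(m)  # noqa: E731
    else:
        draw = lambda: rng.standard_normal(m)  # noqa: E731
    ns = cfg.noise_scale
    beta_crp = beta_crp_true + ns * se_crp * draw()
    beta_sel = beta_sel_true + ns * se_sel * draw()
    beta_out = beta_out_true + ns * se_out * draw()

    ea, oa = _draw_alleles(rng, m)
    span = IL6R_REGION.hi - IL6R_REGION.lo
    pos = np.sort(IL6R_REGION.lo + ((np.arange(m) + 0.5) / m * span).astype(int))
    chrom = IL6R_REGION.chrom
    n_out_total = cfg.n_outcome_case + cfg.n_outcome_control

    exposure = _table(ids, chrom, pos, ea, oa, maf, beta_sel, se_sel,
                      cfg.n_selection, "IL6R_level", "sd_continuous")
    crp = _table(ids, chrom, pos, ea, oa, maf, beta_crp, se_crp,
                 cfg.n_exposure, "CRP", "log_continuous")
    outcome = _table(ids, chrom, pos, ea, oa, maf, beta_out, se_out,
                     n_out_total, "pleural_infection", "log_odds")
    truth = SimTruth(beta_exposure_true=x_true, beta_direct_true=alpha,
                     true_effect=cfg.true_effect, ld=ld, maf=maf, config=cfg)
    return {"exposure": exposure, "crp": crp, "outcome": outcome,
            "ld": ld, "truth": truth}


def instrument_from_sim(sim: dict) -> "Instrument":
    """The whole simulated panel as a CRP-weighted instrument.

    Bypasses the selection filters (every simulated SNP is a true instrument
    by construction) but applies the orientation contract: the effect allele
    is the CRP-lowering allele and ``beta_exposure`` is the per-allele
    decrease in log CRP, so estimates downstream are directly comparable to
    ``SimConfig.true_effect``.  Used for estimator calibration at scale,
    where re-running the full selection pipeline per replicate adds nothing.
    """
    from .instrument import Instrument

    crp = sim["crp"].df
    flip = crp["beta"] > 0  # effect allele written as the CRP-raising one
    df = pd.DataFrame({
        "snp_id": crp["snp_id"],
        "chrom": crp["chrom"],
        "pos": crp["pos"],
        "effect_allele": crp["effect_allele"].where(~flip, crp["other_allele"]),
        "other_allele": crp["other_allele"].where(~flip, crp["effect_allele"]),
        "beta_exposure": crp["beta"].abs(),
        "se_exposure": crp["se"],
        "pval_exposure": crp["pval"],
        "f_stat": (crp["beta"] / crp["se"]) ** 2,
        "eaf": crp["eaf"].where(~flip, 1.0 - crp["eaf"]),
    })
    return Instrument(df)


def make_study_scale_fixture(seed: int, out_dir: str | Path | None = None) -> dict:
    """A 44-SNP instrument-ready dataset at the study's geometry.

    Uses the SimConfig defaults (44 SNPs; 1,601 cases / 830,709 controls;
    true log-OR -1.47) with the given seed.  If ``out_dir`` is given, writes
    the three canonical sumstats TSVs, the LD matrix, and a truth manifest
    JSON (config echo plus per-SNP true effects) computed at generation time.
    """
    cfg = SimConfig(seed=seed)
    sim = simulate_two_sample(cfg)
    sim["region"] = IL6R_REGION
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_sumstats(sim["exposure"], out / "il6r_pqtl.tsv")
        write_sumstats(sim["crp"], out / "crp.tsv")
        write_sumstats(sim["outcome"], out / "outcome.tsv")
        write_ld_matrix(sim["ld"], out / "ld.tsv")
        truth = sim["truth"]
        manifest = {
            "config": asdict(cfg),
            "region": {"chrom": IL6R_REGION.chrom, "start": IL6R_REGION.start,
                       "end": IL6R_REGION.end, "window": IL6R_REGION.window,
                       "build": IL6R_REGION.build},
            "true_effect": truth.true_effect,
            "snp_id": sim["ld"].snp_ids,
            "beta_exposure_true": truth.beta_exposure_true.tolist(),
            "beta_direct_true": truth.beta_direct_true.tolist(),
            "maf": truth.maf.tolist(),
        }
        (out / "truth.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return sim
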