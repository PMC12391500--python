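"""Two-sample MR estimators and sensitivity statistics.

All estimators consume a :class:`~cismr.harmonise.HarmonisedSet` whose
exposure betas (bx) are per-allele decreases in natural-log CRP and whose
outcome betas (by) are log-odds of pleural infection.  The pooled estimate
is therefore a log-odds ratio per unit decrease in log CRP; exponentiation
gives the odds ratio, with OR < 1 reading as protection under IL-6
inhibition.  Estimators never re-flip signs: orientation is fixed once, at
instrument build.

Implemented:

* per-SNP Wald ratios with first-order (optionally second-order) delta SEs,
* fixed-effects inverse-variance-weighted (IVW) pooling — algebraically a
  weighted least-squares fit of by on bx through the origin with weights
  1/by_se²,
* MR-Egger regression (intercept = average directional pleiotropy),
* Cochran's Q heterogeneity with per-SNP contributions,
* radial outlier screening (Bonferroni chi-square(1) on Q contributions,
  iterated),
* leave-one-out IVW,
* the Steiger directionality test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EstimationError
from .harmonise import HarmonisedSet

Z95 = 1.959964  # normal 97.5% quantile, as used for all reported 95% CIs


@dataclass
class WaldEstimate:
    """Single-SNP causal estimate: outcome effect over exposure effect."""

    snp_id: str
    theta: float
    theta_se: float


@dataclass
class MRResult:
    """A pooled causal estimate on the log-odds scale, with its OR transform."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    or_: float = np.nan
    or_low: float = np.nan
    or_high: float = np.nan


@dataclass
class EggerResult:
    slope: float
    slope_se: float
    slope_p: float
    intercept: float
    intercept_se: float
    intercept_p: float
    n_snps: int


@dataclass
class HetStats:
    q: float
    df: int
    pval: float
    per_snp_q: pd.Series


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_correct: bool
    pval: float


@dataclass
class RadialResult:
    outliers: list[str]
    result: MRResult
    n_iterations: int


def _arrays(h: HarmonisedSet):
    v = h.variants
    return (v["bx"].to_numpy(float), v["bx_se"].to_numpy(float),
            v["by"].to_numpy(float), v["by_se"].to_numpy(float),
            v["snp_id"].to_numpy())


def wald_ratio(v, second_order: bool = False) -> WaldEstimate:
    """Wald ratio for one harmonised variant: theta = by/bx.

    The default SE is the first-order delta method, by_se/|bx| — adequate
    when the instrument F-statistic is large, and exactly the SE implied by
    the fixed-effects IVW weights.  ``second_order=True`` adds the
    exposure-uncertainty term sqrt(by_se²/bx² + by²·bx_se²/bx⁴).
    """
    bx, by, by_se = float(v["bx"]), float(v["by"]), float(v["by_se"])
    if bx == 0:
        raise EstimationError(f"Wald ratio undefined for SNP {v['snp_id']}: bx = 0")
    theta = by / bx
    if second_order:
        bx_se = float(v["bx_se"])
        se = np.sqrt(by_se**2 / bx**2 + by**2 * bx_se**2 / bx**4)
    else:
        se = by_se / abs(bx)
    return WaldEstimate(snp_id=str(v["snp_id"]), theta=theta, theta_se=se)


def wald_table(h: HarmonisedSet, second_order: bool = False) -> pd.DataFrame:
    """Per-SNP Wald ratios as a frame (the scatter/forest-plot input)."""
    rows = [wald_ratio(v, second_order) for _, v in h.variants.iterrows()]
    return pd.DataFrame({
        "snp_id": [w.snp_id for w in rows],
        "bx": h.variants["bx"].to_numpy(float),
        "by": h.variants["by"].to_numpy(float),
        "theta": [w.theta for w in rows],
        "theta_se": [w.theta_se for w in rows],
    })


def _result(method: str, beta: float, se: float, n_snps: int,
            pval: float | None = None) -> MRResult:
    if pval is None:
        pval = 2.0 * stats.norm.sf(abs(beta) / se)
    res = MRResult(method=method, beta=beta, se=se,
                   ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
                   pval=float(pval), n_snps=n_snps)
    return to_or(res)


def ivw_fixed(h: HarmonisedSet, method_label: str = "ivw_fe") -> MRResult:
    """Fixed-effects inverse-variance-weighted estimate.

    Pools the per-SNP Wald ratios with weights w_j = bx_j²/by_se_j²
    (the inverse Wald-ratio variances); beta = Σ w θ / Σ w and
    se = sqrt(1/Σ w).  Identical to weighted least squares of by on bx
    through the origin with weights 1/by_se².
    """
    bx, _, by, by_se, _ = _arrays(h)
    if len(bx) == 0:
        raise EstimationError("IVW requires at least one harmonised variant")
    if np.any(bx == 0):
        raise EstimationError("IVW requires all exposure betas nonzero")
    theta = by / bx
    w = bx**2 / by_se**2
    beta = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return _result(method_label, beta, se, len(bx))


def mr_egger(h: HarmonisedSet) -> EggerResult:
    """MR-Egger: weighted regression of by on bx *with* an intercept.

    SNPs are first oriented so bx >= 0 (negating bx and by jointly where
    needed); weights are 1/by_se².  The intercept estimates the average
    directional pleiotropic effect; inference uses the t distribution with
    n-2 degrees of freedom and the multiplicative residual-variance scale.
    """
    bx, _, by, by_se, _ = _arrays(h)
    n = len(bx)
    if n < 3:
        raise EstimationError("MR-Egger needs >= 3 variants (intercept + slope)")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / by_se**2
    X = np.column_stack([np.ones(n), bx])
    XtWX = X.T @ (w[:, None] * X)
    XtWy = X.T @ (w * by)
    coef = np.linalg.solve(XtWX, XtWy)
    resid = by - X @ coef
    s2 = float(np.sum(w * resid**2) / (n - 2))
    cov = s2 * np.linalg.inv(XtWX)
    ses = np.sqrt(np.diag(cov))
    tvals = coef / ses
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - 2)
    return EggerResult(
        slope=float(coef[1]), slope_se=float(ses[1]), slope_p=float(pvals[1]),
        intercept=float(coef[0]), intercept_se=float(ses[0]),
        intercept_p=float(pvals[0]), n_snps=n,
    )


def egger_to_results(e: EggerResult) -> tuple[MRResult, MRResult]:
    """Egger slope and intercept as MRResult rows (slope CI normal-based
    for comparability across the results table; p-values stay t-based)."""
    slope = _result("egger_slope", e.slope, e.slope_se, e.n_snps, pval=e.slope_p)
    icpt = MRResult(method="egger_intercept", beta=e.intercept, se=e.intercept_se,
                    ci_low=e.intercept - Z95 * e.intercept_se,
                    ci_high=e.intercept + Z95 * e.intercept_se,
                    pval=e.intercept_p, n_snps=e.n_snps)
    return slope, icpt


def cochran_q(h: HarmonisedSet, pooled: MRResult) -> HetStats:
    """Cochran's Q about the pooled estimate, with per-SNP contributions."""
    bx, _, by, by_se, ids = _arrays(h)
    theta = by / bx
    w = bx**2 / by_se**2
    per = pd.Series(w * (theta - pooled.beta) ** 2, index=ids)
    q = float(per.sum())
    df = len(bx) - 1
    pval = float(stats.chi2.sf(q, df)) if df >= 1 else np.nan
    return HetStats(q=q, df=df, pval=pval, per_snp_q=per)


def radial_mr(h: HarmonisedSet, alpha: float = 0.05) -> RadialResult:
    """Iterative radial outlier exclusion.

    Each round: fit IVW, compute per-SNP Q contributions, flag SNPs whose
    contribution exceeds the chi-square(1) upper quantile at the
    Bonferroni-corrected level alpha/n, drop them, refit.  Stops when no new
    outlier appears or only two SNPs remain.
    """
    if len(h) < 3:
        raise EstimationError("radial MR needs >= 3 variants")
    current = h
    outliers: list[str] = []
    n_iter = 0
    while True:
        n_iter += 1
        res = ivw_fixed(current, method_label="radial_ivw")
        het = cochran_q(current, res)
        cut = stats.chi2.isf(alpha / len(current), df=1)
        flagged = het.per_snp_q[het.per_snp_q > cut].index.tolist()
        if not flagged or len(current) - len(flagged) < 2:
            if flagged and len(current) - len(flagged) < 2:
                if len(flagged) == len(current):
                    raise EstimationError("radial MR flagged every SNP as an outlier")
            break
        outliers.extend(flagged)
        keep = ~current.variants["snp_id"].isin(flagged)
        current = replace(current, variants=current.variants.loc[keep].reset_index(drop=True))
    return RadialResult(outliers=outliers, result=res, n_iterations=n_iter)


def leave_one_out(h: HarmonisedSet) -> list[tuple[str, MRResult]]:
    """IVW re-estimated with each SNP excluded in turn."""
    if len(h) < 2:
        raise EstimationError("leave-one-out needs >= 2 variants")
    out = []
    for snp in h.variants["snp_id"]:
        keep = h.variants["snp_id"] != snp
        sub = replace(h, variants=h.variants.loc[keep].reset_index(drop=True))
        out.append((str(snp), ivw_fixed(sub, method_label="loo_ivw")))
    return out


def steiger_test(
    h: HarmonisedSet,
    n_exposure: int,
    ncase: int,
    ncontrol: int,
) -> SteigerResult:
    """Directionality check: does the instrument explain more variance in the
    exposure than in the outcome?

    Exposure r² per SNP comes from the t-statistic transform
    r² = t²/(t² + n - 2) with t = bx/bx_se.  For the binary outcome the
    per-SNP log-OR is converted to an observed-scale correlation through the
    linear-probability approximation at the study case fraction φ:
    r² ≈ by²·2p(1-p)·φ(1-φ).  Summed r² are compared via a z-test on
    Fisher-transformed correlations.
    """
    if min(n_exposure, ncase, ncontrol) <= 10:
        raise EstimationError(
            "Steiger test requires exposure and outcome sample sizes; supply "
            "n_exposure, ncase and ncontrol in the run config"
        )
    bx, bx_se, by, _, _ = _arrays(h)
    t = bx / bx_se
    r2_exp = float(np.sum(t**2 / (t**2 + n_exposure - 2)))

    n_out = ncase + ncontrol
    phi = ncase / n_out
    eaf = h.variants["eaf_outcome"].fillna(h.variants["eaf_exposure"]).to_numpy(float)
    if np.isnan(eaf).any():
        raise EstimationError("Steiger outcome r2 needs allele frequencies")
    r2_out = float(np.sum(by**2 * 2 * eaf * (1 - eaf) * phi * (1 - phi)))

    r2_exp_c = min(r2_exp, 1.0)
    r2_out_c = min(r2_out, 1.0)
    z = (np.arctanh(np.sqrt(r2_exp_c)) - np.arctanh(np.sqrt(r2_out_c))) / np.sqrt(
        1.0 / (n_exposure - 3) + 1.0 / (n_out - 3)
    )
    pval = float(2.0 * stats.norm.sf(abs(z)))
    return SteigerResult(r2_exposure=r2_exp_c, r2_outcome=r2_out_c,
                         direction_correct=bool(r2_exp_c > r2_out_c), pval=pval)


def to_or(result: MRResult) -> MRResult:
    """Fill the odds-ratio fields by exponentiating beta and its CI bounds."""
    result.or_ = float(np.exp(result.beta))
    result.or_low = float(np.exp(result.ci_low))
    result.or_high = float(np.exp(result.ci_high))
    return result


def results_table(results: list[MRResult]) -> pd.DataFrame:
    """One row per analysis: the forest-plot input TSV."""
    return pd.DataFrame([{
        "method": r.method, "n_snps": r.n_snps, "beta": r.beta, "se": r.se,
        "ci_low": r.ci_low, "ci_high": r.ci_high, "pval": r.pval,
        "or": r.or_, "or_low": r.or_low, "or_high": r.or_high,
    } for r in results])
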