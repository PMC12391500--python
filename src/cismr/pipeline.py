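"""Config-driven orchestration of the full analysis.

One :func:`run` reproduces the primary analysis and every sensitivity
analysis in a single pass:

1. primary — clump at r² 0.1, fixed-effects IVW;
2. stricter independence — re-clump at r² 0.01, IVW;
3. dual-pQTL restriction — instrument SNPs also genome-wide significant for
   CRP, IVW;
4. radial outlier exclusion, IVW on the retained SNPs;
5. leave-one-out IVW (reported as its own table; the summary row is the
   exclusion that costs the most precision);
6. MR-Egger slope and intercept;
7. Steiger directionality.

Outputs are plain TSV/JSON, deterministic byte-for-byte for a given config:
a results table (one row per analysis), the harmonisation audit, the
leave-one-out table, the per-SNP Wald table (scatter/forest input), a
narrative run log, and a machine-readable JSON sidecar of every threshold
and count.  Any stage failure removes partial outputs and re-raises with
the stage name.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace as _replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from .exceptions import CisMRError, ConfigurationError
from .harmonise import harmonise
from .instrument import (GeneRegion, _clump_frame, build_instrument,
                         restrict_dual_pqtl)
from .ld import read_ld_matrix
from .sumstats import read_sumstats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one analysis run needs; loadable from a single YAML file."""

    exposure_path: str
    crp_path: str
    outcome_path: str
    ld_path: str
    out_dir: str
    region: GeneRegion
    p_threshold: float = 5e-8
    r2_threshold: float = 0.1
    r2_threshold_strict: float = 0.01
    f_threshold: float = 10.0
    palindrome_eaf_limit: float = 0.42
    radial_alpha: float = 0.05
    n_exposure: int | None = None
    ncase: int | None = None
    ncontrol: int | None = None
    seed: int = 0
    column_maps: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        region = GeneRegion(**raw.pop("region"))
        return cls(region=region, **raw)

    def validate(self) -> None:
        for key in ("exposure_path", "crp_path", "outcome_path", "ld_path"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise ConfigurationError(f"{key} does not exist: {p}")
        for name, val, lo, hi in [
            ("p_threshold", self.p_threshold, 0, 1),
            ("r2_threshold", self.r2_threshold, 0, 1),
            ("r2_threshold_strict", self.r2_threshold_strict, 0, 1),
            ("palindrome_eaf_limit", self.palindrome_eaf_limit, 0, 0.5),
            ("radial_alpha", self.radial_alpha, 0, 1),
        ]:
            if not (lo < val < hi):
                raise ConfigurationError(f"{name}={val} outside ({lo}, {hi})")


OUTPUT_FILES = ("results.tsv", "harmonisation_audit.tsv", "leave_one_out.tsv",
                "wald_per_snp.tsv", "run_log.txt", "counts.json")


def _fmt_result(r: est.MRResult) -> str:
    return (f"{r.method}: n={r.n_snps} beta={r.beta:.4f} se={r.se:.4f} "
            f"OR={r.or_:.3f} ({r.or_low:.3f}-{r.or_high:.3f}) p={r.pval:.3g}")


def run(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the in-memory report bundle and
    writes all output files under ``cfg.out_dir``."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    counts: dict = {"thresholds": {
        "p_threshold": cfg.p_threshold, "r2_threshold": cfg.r2_threshold,
        "r2_threshold_strict": cfg.r2_threshold_strict,
        "f_threshold": cfg.f_threshold,
        "palindrome_eaf_limit": cfg.palindrome_eaf_limit,
        "radial_alpha": cfg.radial_alpha, "window_bp": cfg.region.window,
        "region": f"{cfg.region.chrom}:{cfg.region.start}-{cfg.region.end}",
    }}

    def note(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    try:
        stage = "load_inputs"
        exposure = read_sumstats(cfg.exposure_path,
                                 cfg.column_maps.get("exposure"),
                                 trait_scale="sd_continuous", trait_label="IL6R")
        crp = read_sumstats(cfg.crp_path, cfg.column_maps.get("crp"),
                            trait_scale="log_continuous", trait_label="CRP")
        outcome = read_sumstats(cfg.outcome_path, cfg.column_maps.get("outcome"),
                                trait_scale="log_odds", trait_label="outcome")
        ld = read_ld_matrix(cfg.ld_path)
        note(f"loaded exposure={len(exposure)} crp={len(crp)} "
             f"outcome={len(outcome)} ld={len(ld)} SNPs")

        stage = "build_instrument"
        instr = build_instrument(exposure, crp, cfg.region, ld,
                                 p_threshold=cfg.p_threshold,
                                 r2_threshold=cfg.r2_threshold,
                                 f_threshold=cfg.f_threshold,
                                 palindrome_eaf_limit=cfg.palindrome_eaf_limit)
        counts["instrument"] = instr.audit
        note(f"instrument: {len(instr)} SNPs after stages {instr.audit}")

        stage = "harmonise"
        hset = harmonise(instr, outcome, cfg.palindrome_eaf_limit)
        counts["harmonisation"] = hset.audit
        note(f"harmonised: {len(hset)} SNPs retained ({hset.audit})")

        stage = "primary_ivw"
        primary = est.ivw_fixed(hset, method_label="ivw_fe")
        note(_fmt_result(primary))

        stage = "strict_clump"
        # re-clump the instrument itself at the stricter threshold
        strict_instr_df = instr.df.rename(columns={"pval_selection": "pval"})
        strict_df = _clump_frame(strict_instr_df, ld, cfg.r2_threshold_strict)
        strict_ids = set(strict_df["snp_id"])
        keep = hset.variants["snp_id"].isin(strict_ids)
        h_strict = _replace(hset, variants=hset.variants.loc[keep]
                            .reset_index(drop=True))
        strict = est.ivw_fixed(h_strict, method_label="ivw_fe_strict_clump")
        counts["strict_clump_n"] = int(len(h_strict))
        note(_fmt_result(strict))

        stage = "dual_pqtl"
        dual_instr = restrict_dual_pqtl(instr, crp, cfg.p_threshold)
        keep = hset.variants["snp_id"].isin(set(dual_instr.snp_ids))
        h_dual = _replace(hset, variants=hset.variants.loc[keep]
                          .reset_index(drop=True))
        dual = est.ivw_fixed(h_dual, method_label="ivw_fe_dual_pqtl")
        counts["dual_pqtl_n"] = int(len(h_dual))
        note(_fmt_result(dual))

        stage = "radial"
        radial = est.radial_mr(hset, alpha=cfg.radial_alpha)
        counts["radial_outliers"] = radial.outliers
        note(f"radial: removed {len(radial.outliers)} outliers "
             f"in {radial.n_iterations} iterations")
        note(_fmt_result(radial.result))

        stage = "leave_one_out"
        loo = est.leave_one_out(hset)
        loo_df = pd.DataFrame([{
            "excluded_snp": snp, "n_snps": r.n_snps, "beta": r.beta, "se": r.se,
            "ci_low": r.ci_low, "ci_high": r.ci_high, "pval": r.pval,
            "or": r.or_, "or_low": r.or_low, "or_high": r.or_high,
        } for snp, r in loo])
        worst_snp, worst = max(loo, key=lambda t: t[1].se)
        worst.method = f"loo_ivw_excl_{worst_snp}"
        note(f"leave-one-out: widest CI when excluding {worst_snp}")
        note(_fmt_result(worst))

        stage = "egger"
        egger = est.mr_egger(hset)
        slope_row, _icpt_row = est.egger_to_results(egger)
        counts["egger_intercept"] = {
            "estimate": egger.intercept, "se": egger.intercept_se,
            "pval": egger.intercept_p,
        }
        note(f"egger: intercept={egger.intercept:.4f} "
             f"(se {egger.intercept_se:.4f}, p={egger.intercept_p:.3f})")
        note(_fmt_result(slope_row))

        stage = "steiger"
        if None in (cfg.n_exposure, cfg.ncase, cfg.ncontrol):
            raise ConfigurationError(
                "Steiger test needs n_exposure, ncase and ncontrol in the config"
            )
        steiger = est.steiger_test(hset, cfg.n_exposure, cfg.ncase, cfg.ncontrol)
        counts["steiger"] = {
            "r2_exposure": steiger.r2_exposure, "r2_outcome": steiger.r2_outcome,
            "direction_correct": steiger.direction_correct, "pval": steiger.pval,
        }
        note(f"steiger: r2_exposure={steiger.r2_exposure:.4g} "
             f"r2_outcome={steiger.r2_outcome:.4g} "
             f"direction_correct={steiger.direction_correct} p={steiger.pval:.3g}")

        stage = "write_outputs"
        steiger_row = est.MRResult(
            method="steiger_direction_correct" if steiger.direction_correct
            else "steiger_direction_reversed",
            beta=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
            pval=steiger.pval, n_snps=len(hset))
        results = [primary, strict, dual, radial.result, worst,
                   slope_row, steiger_row]
        res_df = est.results_table(results)
        res_df.to_csv(out / "results.tsv", sep="\t", index=False, na_rep="NA")
        hset.write_audit(out / "harmonisation_audit.tsv")
        loo_df.to_csv(out / "leave_one_out.tsv", sep="\t", index=False)
        est.wald_table(hset).to_csv(out / "wald_per_snp.tsv", sep="\t",
                                    index=False)
        (out / "counts.json").write_text(
            json.dumps(counts, indent=2, default=str) + "\n")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    except CisMRError as exc:
        for f in OUTPUT_FILES:
            (out / f).unlink(missing_ok=True)
        raise CisMRError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return {
        "instrument": instr, "harmonised": hset, "results": results,
        "results_table": res_df, "leave_one_out": loo_df,
        "radial": radial, "egger": egger, "steiger": steiger, "counts": counts,
    }
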