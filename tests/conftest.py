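"""Shared builders for hand-written summary-statistics fixtures."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cismr.harmonise import HarmonisedSet
from cismr.sumstats import CANONICAL_COLUMNS, SumStats

DEFAULTS = {
    "chrom": "1",
    "pos": 1000,
    "effect_allele": "A",
    "other_allele": "G",
    "eaf": 0.3,
    "beta": 0.1,
    "se": 0.01,
    "pval": 1e-12,
    "n": 10_000,
}


def make_sumstats(rows, trait_scale="log_continuous", trait_label="trait"):
    """Build a SumStats from a list of per-SNP dicts; unstated fields get
    sensible defaults, snp_id defaults to rs1, rs2, ..."""
    full = []
    for i, row in enumerate(rows):
        rec = dict(DEFAULTS, snp_id=f"rs{i + 1}")
        rec.update(row)
        full.append(rec)
    df = pd.DataFrame(full)[CANONICAL_COLUMNS]
    return SumStats(df, trait_label=trait_label, trait_scale=trait_scale)


def make_harmonised(bx, by, by_se, bx_se=None, eaf=0.3):
    """HarmonisedSet straight from effect arrays (already oriented)."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    by_se = np.asarray(by_se, float)
    bx_se = np.full_like(bx, 1e-3) if bx_se is None else np.asarray(bx_se, float)
    n = len(bx)
    variants = pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(n)],
        "effect_allele": "A", "other_allele": "G",
        "bx": bx, "bx_se": bx_se, "by": by, "by_se": by_se,
        "eaf_exposure": eaf, "eaf_outcome": eaf,
        "status": "aligned",
    })
    return HarmonisedSet(variants=variants, audit={"aligned": n})


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
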