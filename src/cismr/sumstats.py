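"""GWAS summary-statistics containers and I/O.

The universal interchange object is :class:`SumStats`: a validated pandas
DataFrame in canonical column order plus trait metadata.  All downstream
stages (instrument selection, harmonisation, estimation) consume and produce
this object, so validation happens exactly once, at parse time.

Conventions
-----------
* Coordinates are 1-based, as in GWAS summary-statistics exports.  The genome
  build is metadata carried on the table (``genome_build``), never inferred.
* Only biallelic SNPs are accepted: alleles must be single bases in
  {A, C, G, T} and the two alleles must differ.  Indels and multi-allelic
  records are dropped at parse time.
* ``beta`` is the additive effect per copy of ``effect_allele`` on the trait
  scale declared by ``trait_scale`` (natural-log units, trait SD units, or
  log-odds for case-control GWAS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyResultError

logger = logging.getLogger(__name__)

#: Canonical column order for every SumStats frame and for the TSV on disk.
CANONICAL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

#: Columns that must be present (directly or via the column map).
MANDATORY = ["snp_id", "effect_allele", "other_allele", "beta", "se", "pval"]

TRAIT_SCALES = ("log_continuous", "sd_continuous", "log_odds")

VALID_BASES = frozenset("ACGT")


@dataclass
class SumStats:
    """One GWAS: per-SNP effect estimates with alleles and frequencies.

    Parameters
    ----------
    df
        DataFrame with the canonical columns.  ``snp_id`` is unique.
    trait_label
        Human-readable trait name, echoed in logs and output headers.
    trait_scale
        One of ``log_continuous`` (effect on the natural log of the trait),
        ``sd_continuous`` (effect in trait standard deviations) or
        ``log_odds`` (case-control log odds ratio).
    genome_build
        Optional build tag (e.g. ``GRCh37``); carried, never inferred.
    audit
        Per-reason counts of rows dropped during validation.
    """

    df: pd.DataFrame
    trait_label: str = ""
    trait_scale: str = "log_continuous"
    genome_build: str | None = None
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_scale not in TRAIT_SCALES:
            raise ConfigurationError(
                f"trait_scale must be one of {TRAIT_SCALES}, got {self.trait_scale!r}"
            )
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"SumStats frame missing columns: {missing}")
        if self.df["snp_id"].duplicated().any():
            dups = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"].head(5)
            raise ConfigurationError(
                f"duplicate snp_id in table (first few: {list(dups)})"
            )
        self.df = self.df[CANONICAL_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df["snp_id"])

    def subset(self, snp_ids, *, stage: str = "subset") -> "SumStats":
        """Rows whose snp_id is in ``snp_ids``, preserving this table's order."""
        keep = self.df["snp_id"].isin(set(snp_ids))
        if not keep.any():
            raise EmptyResultError(stage, f"none of {len(set(snp_ids))} ids present")
        return replace(self, df=self.df.loc[keep].reset_index(drop=True))


def _validate_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Enforce per-record invariants, dropping and counting offending rows."""
    audit: dict[str, int] = {}
    n0 = len(df)

    df = df.copy()
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper().str.strip()
    df["other_allele"] = df["other_allele"].astype(str).str.upper().str.strip()
    for col in ("beta", "se", "pval", "eaf", "pos", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str).str.replace("^chr", "", regex=True)

    ok_alleles = (
        df["effect_allele"].isin(VALID_BASES)
        & df["other_allele"].isin(VALID_BASES)
        & (df["effect_allele"] != df["other_allele"])
    )
    ok_beta = np.isfinite(df["beta"])
    ok_se = np.isfinite(df["se"]) & (df["se"] > 0)
    ok_pval = np.isfinite(df["pval"]) & (df["pval"] > 0) & (df["pval"] <= 1)
    ok_eaf = df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1))

    for name, mask in [
        ("invalid_alleles", ~ok_alleles),
        ("invalid_beta", ~ok_beta),
        ("invalid_se", ~ok_se),
        ("invalid_pval", ~ok_pval),
        ("invalid_eaf", ~ok_eaf),
    ]:
        n_bad = int(mask.sum())
        if n_bad:
            audit[name] = n_bad
    df = df[ok_alleles & ok_beta & ok_se & ok_pval & ok_eaf]

    # Duplicate snp_id: keep the lowest p-value, log the rest.
    if df["snp_id"].duplicated().any():
        before = len(df)
        df = df.sort_values("pval", kind="stable").drop_duplicates("snp_id")
        audit["duplicate_snp_id"] = before - len(df)
        # restore input order of the survivors
        df = df.sort_index()

    audit["n_input"] = n0
    audit["n_valid"] = len(df)
    return df.reset_index(drop=True), audit


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_scale: str = "log_continuous",
    trait_label: str = "",
    genome_build: str | None = None,
    sep: str | None = None,
) -> SumStats:
    """Read a delimited summary-statistics file into a validated table.

    ``column_map`` maps canonical field names to source column headers, e.g.
    ``{"snp_id": "rsid", "beta": "Effect"}``; unmapped canonical names are
    looked up verbatim.  Rows violating record invariants (non-ACGT or equal
    alleles, ``se <= 0``, p-value outside (0, 1], allele frequency outside
    [0, 1]) are dropped and counted in ``SumStats.audit``.

    Raises
    ------
    ConfigurationError
        A mandatory column is absent after applying the map.
    EmptyResultError
        No row survives validation.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    column_map = dict(column_map or {})
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src in df.columns:
            rename[src] = canon
        elif canon in MANDATORY:
            raise ConfigurationError(
                f"mandatory column {canon!r} (source name {src!r}) not found in "
                f"{path}; available: {list(df.columns)}"
            )
    df = df.rename(columns=rename)
    for canon in CANONICAL_COLUMNS:
        if canon not in df.columns:
            df[canon] = np.nan

    clean, audit = _validate_frame(df[CANONICAL_COLUMNS])
    n_dropped = audit["n_input"] - audit["n_valid"]
    if n_dropped:
        logger.info("read_sumstats(%s): dropped %d/%d rows: %s",
                    path, n_dropped, audit["n_input"], audit)
    if len(clean) == 0:
        raise EmptyResultError("read_sumstats", f"no valid rows in {path}")
    return SumStats(clean, trait_label=trait_label, trait_scale=trait_scale,
                    genome_build=genome_build, audit=audit)


def write_sumstats(table: SumStats, path) -> None:
    """Write the canonical TSV (fixed column order, tab-separated)."""
    table.df[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def intersect(a: SumStats, b: SumStats) -> tuple[SumStats, SumStats]:
    """Pair the two tables on shared ``snp_id``, preserving ``a``'s order.

    Returns the two tables restricted to the common SNPs, rows aligned.

    Raises
    ------
    EmptyResultError
        The ID sets are disjoint; the message lists up to five sample IDs
        from each side as a diagnostic.
    """
    shared = set(a.df["snp_id"]) & set(b.df["snp_id"])
    n_only_a = len(a) - len(shared)
    n_only_b = len(b) - len(shared)
    if not shared:
        raise EmptyResultError(
            "intersect",
            f"no shared snp_ids; a has e.g. {a.snp_ids[:5]}, b has e.g. {b.snp_ids[:5]}",
        )
    if n_only_a or n_only_b:
        logger.info("intersect: %d shared, %d only in a, %d only in b",
                    len(shared), n_only_a, n_only_b)
    a_sub = a.df[a.df["snp_id"].isin(shared)].reset_index(drop=True)
    b_sub = b.df.set_index("snp_id").loc[a_sub["snp_id"]].reset_index()
    return (
        replace(a, df=a_sub),
        replace(b, df=b_sub[CANONICAL_COLUMNS]),
    )
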