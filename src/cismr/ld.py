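"""Pairwise-LD correlation matrices.

Clumping consumes the squared correlation r**2; the simulator uses the signed
correlation r.  The matrix is stored dense — cis instruments are a few dozen
SNPs, so there is nothing to gain from sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

SYMMETRY_TOL = 1e-8


@dataclass
class LDMatrix:
    """Pairwise SNP correlation (r, signed) for an ordered SNP panel."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.snp_ids)
        if self.r.shape != (m, m):
            raise ConfigurationError(
                f"LD matrix shape {self.r.shape} does not match {m} snp_ids"
            )
        if not np.allclose(self.r, self.r.T, atol=1e-12, rtol=0):
            raise ConfigurationError("LD matrix is not symmetric within 1e-12")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12, rtol=0):
            raise ConfigurationError("LD matrix diagonal must be exactly 1")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ConfigurationError("LD matrix entries must satisfy |r| <= 1")

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def r2(self) -> np.ndarray:
        return self.r ** 2

    def subset(self, snp_ids) -> "LDMatrix":
        """Restrict and reorder to ``snp_ids``; all must be present."""
        missing = [s for s in snp_ids if s not in self._index]
        if missing:
            raise ConfigurationError(f"SNPs absent from LD matrix: {missing}")
        idx = [self._index[s] for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])

    @property
    def _index(self) -> dict:
        return {s: i for i, s in enumerate(self.snp_ids)}


def read_ld_matrix(path, snp_ids=None, sep: str = "\t") -> LDMatrix:
    """Read a square delimited correlation matrix with a SNP-id header.

    Mild numerical asymmetry (<= 1e-8, e.g. from printed precision) is
    repaired by averaging; anything larger is treated as a corrupt input.
    If ``snp_ids`` is given the matrix is subset and reordered to it.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    r = df.to_numpy(dtype=float)
    asym = np.max(np.abs(r - r.T)) if r.size else 0.0
    if asym > SYMMETRY_TOL:
        raise ConfigurationError(
            f"LD matrix asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL}"
        )
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    ld = LDMatrix([str(s) for s in df.columns], r)
    if snp_ids is not None:
        ld = ld.subset(list(snp_ids))
    return ld


def write_ld_matrix(ld: LDMatrix, path, sep: str = "\t") -> None:
    pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids).to_csv(path, sep=sep)
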