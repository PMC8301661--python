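"""Sample-overlap correlation of GWAS summary statistics.

When the outcome and exposure GWAS cohorts share participants, the
estimation errors of (Γ̂_j, γ̂_j) are correlated, identically across SNPs:
for shared sample count N_s, cohort sizes N_o and N_ek, the error
correlation is N_s/√(N_ek·N_o)·Corr[Y_s, X_ks].  That (K+1)×(K+1)
correlation matrix Σ is estimated from SNPs that are null for every
exposure — all selection p-values ≥ 0.5 — whose Z-values are then pure
noise with exactly this correlation structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import HarmonizedStudy

logger = logging.getLogger(__name__)


@dataclass
class SharedCorrelation:
    """Estimated overlap correlation Σ; row/column 0 is the outcome."""

    matrix: np.ndarray
    n_null_snps: int = 0
    trait_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("Σ must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("Σ must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValueError("Σ must have unit diagonal")
        if np.any(np.abs(m) > 1 + 1e-8):
            raise ValueError("Σ entries must lie in [-1, 1]")
        self.matrix = m

    @property
    def K(self) -> int:
        return self.matrix.shape[0] - 1

    @property
    def theta(self) -> float:
        """Outcome–exposure correlation for the single-exposure case."""
        return float(self.matrix[0, 1])

    @classmethod
    def identity(cls, K: int) -> "SharedCorrelation":
        """No cohort overlap: independent estimation errors."""
        return cls(matrix=np.eye(K + 1), n_null_snps=0)

    def to_tsv(self, path) -> None:
        names = self.trait_names or [f"trait{i}" for i in range(self.K + 1)]
        pd.DataFrame(self.matrix, index=names, columns=names).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SharedCorrelation":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(matrix=df.to_numpy(), trait_names=list(df.columns))


def nearest_psd_correlation(matrix: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Clip negative eigenvalues and rescale back to unit diagonal."""
    w, v = np.linalg.eigh(matrix)
    w = np.clip(w, eig_floor, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2


def estimate_shared_correlation(
    study: HarmonizedStudy,
    null_p_cutoff: float = 0.5,
    min_null_snps: int = 100,
) -> SharedCorrelation:
    """Estimate Σ from the sample correlation of null-SNP Z-values.

    SNPs with every selection p-value ≥ ``null_p_cutoff`` form the null
    panel; the T×(K+1) matrix of Z-values (outcome first) is formed and
    its sample correlation returned, PSD-repaired if the plug-in estimate
    is indefinite (logged).
    """
    sel = study.sel_pvalues
    mask = np.all(sel >= null_p_cutoff, axis=1)
    T = int(mask.sum())
    if T < min_null_snps:
        raise ValueError(
            f"only {T} SNPs have all selection p-values >= {null_p_cutoff}; "
            f"at least {min_null_snps} are needed — supply a larger SNP panel"
        )
    z = np.column_stack([
        study.Gamma[mask] / study.se_Gamma[mask],
        study.gamma[mask] / study.se_gamma[mask],
    ])
    corr = np.corrcoef(z, rowvar=False)
    corr = np.clip((corr + corr.T) / 2, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    eigs = np.linalg.eigvalsh(corr)
    if eigs.min() < 0:
        logger.info("shared correlation estimate indefinite (min eig %.3g); "
                    "projecting to nearest PSD correlation", eigs.min())
        corr = nearest_psd_correlation(corr)
    return SharedCorrelation(matrix=corr, n_null_snps=T,
                             trait_names=list(study.trait_names))
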