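"""Core data containers: count matrices, design matrices, and per-gene effect tables.

Orientation is fixed as observations x genes everywhere (i indexes
observations -- cells or pseudo-bulk samples -- and j indexes genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "DesignMatrix", "GeneEffectTable"]

RESULT_COLUMNS = [
    "gene",
    "tau_hat",
    "sigma_hat",
    "T",
    "p",
    "q",
    "reject_fdr",
    "reject_fdx",
]


def _check_ids(ids: Sequence, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass
class CountMatrix:
    """Non-negative integer expression counts with identifiers and size factors.

    Attributes
    ----------
    counts : (n, p) ndarray
        Observed counts Y, observations x genes.
    obs_ids, gene_ids : sequences of identifiers (unique).
    size_factors : (n,) ndarray or None
        Per-observation sequencing-depth factors s_i; strictly positive and
        renormalized to mean 1 once estimated.
    """

    counts: np.ndarray
    obs_ids: Optional[Sequence] = None
    gene_ids: Optional[Sequence] = None
    size_factors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        Y = np.asarray(self.counts)
        if Y.ndim != 2:
            raise ValueError("counts must be a 2-D observations x genes matrix")
        if not np.all(np.isfinite(Y.astype(float))):
            raise ValueError("counts contain NaN or infinite entries")
        if np.any(Y < 0):
            raise ValueError("counts contain negative entries")
        if not np.allclose(Y, np.round(Y)):
            raise ValueError("counts contain non-integer entries")
        self.counts = np.asarray(np.round(Y), dtype=np.int64)
        n, p = self.counts.shape
        if self.obs_ids is None:
            self.obs_ids = np.array([f"obs{i}" for i in range(n)], dtype=object)
        if self.gene_ids is None:
            self.gene_ids = np.array([f"gene{j}" for j in range(p)], dtype=object)
        self.obs_ids = _check_ids(self.obs_ids, "observation")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        if len(self.obs_ids) != n or len(self.gene_ids) != p:
            raise ValueError("identifier lengths do not match count dimensions")
        if self.size_factors is not None:
            s = np.asarray(self.size_factors, dtype=float)
            if s.shape != (n,) or np.any(s <= 0) or not np.all(np.isfinite(s)):
                raise ValueError("size_factors must be n strictly positive reals")
            self.size_factors = s

    @property
    def n_obs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class DesignMatrix:
    """Treatment assignment plus observed covariates.

    ``treatment`` is binary {0, 1} or categorical with a designated
    ``control_label``; ``covariates`` is an (n, d) real matrix (d may be 0).
    """

    treatment: np.ndarray
    covariates: Optional[np.ndarray] = None
    covariate_names: Optional[Sequence[str]] = None
    control_label: Optional[object] = None

    def __post_init__(self) -> None:
        A = np.asarray(self.treatment)
        if A.ndim != 1:
            raise ValueError("treatment must be a 1-D vector")
        levels, counts = np.unique(A, return_counts=True)
        if len(levels) < 2:
            raise ValueError("treatment must have at least 2 levels")
        if np.any(counts < 2):
            raise ValueError("every treatment level needs at least 2 observations")
        self.treatment = A
        n = len(A)
        if self.covariates is None:
            self.covariates = np.zeros((n, 0))
        X = np.asarray(self.covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != n:
            raise ValueError("covariates and treatment disagree on n")
        if not np.all(np.isfinite(X)):
            raise ValueError("covariates contain NaN or infinite values")
        if X.shape[1] > 0:
            aug = np.column_stack([np.ones(n), X])
            if np.linalg.matrix_rank(aug) < aug.shape[1]:
                raise ValueError("covariate matrix is rank deficient after intercept")
        self.covariates = X
        if self.covariate_names is None:
            self.covariate_names = [f"x{k}" for k in range(X.shape[1])]
        if len(self.covariate_names) != X.shape[1]:
            raise ValueError("covariate_names length mismatch")

    @property
    def is_binary(self) -> bool:
        levels = set(np.unique(self.treatment).tolist())
        return levels <= {0, 1}

    def binary_indicator(self) -> np.ndarray:
        """Treatment as a {0,1} float vector (requires binary treatment)."""
        if not self.is_binary:
            raise ValueError(
                "treatment is categorical; use run_contrasts for multi-level designs"
            )
        return np.asarray(self.treatment, dtype=float)

    @property
    def n_obs(self) -> int:
        return len(self.treatment)


@dataclass
class GeneEffectTable:
    """Per-gene causal log-fold-change estimates and test results."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RESULT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"result table missing columns: {missing}")
        self.table = self.table[RESULT_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_arrays(
        cls,
        gene_ids,
        tau_hat,
        sigma_hat,
        T,
        p,
        q,
        reject_fdr,
        reject_fdx,
        metadata: Optional[dict] = None,
    ) -> "GeneEffectTable":
        df = pd.DataFrame(
            {
                "gene": np.asarray(gene_ids, dtype=object),
                "tau_hat": np.asarray(tau_hat, dtype=float),
                "sigma_hat": np.asarray(sigma_hat, dtype=float),
                "T": np.asarray(T, dtype=float),
                "p": np.asarray(p, dtype=float),
                "q": np.asarray(q, dtype=float),
                "reject_fdr": np.asarray(reject_fdr, dtype=bool),
                "reject_fdx": np.asarray(reject_fdx, dtype=bool),
            }
        )
        return cls(df, metadata or {})
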