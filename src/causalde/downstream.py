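"""Counterfactual-distribution summaries and conditional treatment effects.

Both operations consume imputed potential outcomes. Counterfactual
summaries report quantiles and means of log(Yhat(a) + pseudo_count) per arm.
CATE curves smooth each arm of a gene's potential outcomes against a
conditioning covariate (e.g. age) with a tricube local-linear (LOESS-style)
smoother and report the log-ratio of the two smooths on an equispaced grid,
with percentile bootstrap confidence bands. Smoothing the arm means before
taking the log-ratio avoids logs of non-positive per-observation values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .effects import PotentialOutcomes

__all__ = ["CateCurve", "counterfactual_summary", "estimate_cate"]

_QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)


@dataclass
class CateCurve:
    """Conditional LFC curve with pointwise 95% bootstrap bands."""

    covariate_grid: np.ndarray
    estimate: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    span: float
    n_boot: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grid": self.covariate_grid,
                "estimate": self.estimate,
                "lo": self.ci_lower,
                "hi": self.ci_upper,
            }
        )


def counterfactual_summary(
    po: PotentialOutcomes, genes, pseudo_count: float = 1.0
) -> pd.DataFrame:
    """Per-gene quantiles/means of log(Yhat(a) + pseudo_count) for both arms."""
    genes = np.atleast_1d(np.asarray(genes, dtype=int))
    p = po.y1_hat.shape[1]
    if np.any((genes < 0) | (genes >= p)):
        raise IndexError("gene index out of range")
    rows = []
    for j in genes:
        for arm, mat in ((0, po.y0_hat), (1, po.y1_hat)):
            vals = np.log(mat[:, j] + pseudo_count)
            row = {"gene": int(j), "arm": arm, "mean": float(vals.mean())}
            for q in _QUANTILES:
                row[f"q{int(100 * q)}"] = float(np.quantile(vals, q))
            rows.append(row)
    return pd.DataFrame(rows)


def _smooth_arm(y: np.ndarray, v: np.ndarray, grid: np.ndarray, span: float) -> np.ndarray:
    out = lowess(y, v, frac=span, it=0, xvals=grid)
    return np.asarray(out, dtype=float)


def estimate_cate(
    po: PotentialOutcomes,
    gene: int,
    v: np.ndarray,
    span: float = 0.75,
    n_boot: int = 200,
    n_grid: int = 50,
    seed: int = 0,
) -> CateCurve:
    """Conditional LFC tau_j(v0) = log(s1(v0) / s0(v0)) along covariate v.

    Each arm's potential outcomes are smoothed against v (tricube weights,
    local degree 1, span fraction of the data); the 95% band is a percentile
    bootstrap over observations. Grid points with fewer than 5 neighbors
    inside the smoothing window, or a non-positive smoothed arm mean, yield
    NaN (uncertainty near the boundaries is genuinely wider).
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("conditioning covariate must be finite")
    n = len(v)
    if n < 20:
        raise ValueError("need at least 20 observations for CATE smoothing")
    y1 = po.y1_hat[:, gene]
    y0 = po.y0_hat[:, gene]
    grid = np.linspace(v.min(), v.max(), n_grid)

    k = max(int(np.ceil(span * n)), 2)
    dist = np.abs(grid[:, None] - v[None, :])
    bandwidth = np.sort(dist, axis=1)[:, k - 1]
    neighbors = (dist <= bandwidth[:, None]).sum(axis=1)
    sparse = neighbors < 5
    if sparse.any():
        warnings.warn(
            f"{int(sparse.sum())} grid points with < 5 effective neighbors -> NaN",
            stacklevel=2,
        )

    v_scale = 1.0 + np.abs(v).max()

    def curve(idx: np.ndarray) -> np.ndarray:
        if np.ptp(v[idx]) < 1e-8 * v_scale:
            # degenerate covariate: the local fit collapses to the arm means
            s1 = np.full(len(grid), y1[idx].mean())
            s0 = np.full(len(grid), y0[idx].mean())
        else:
            s1 = _smooth_arm(y1[idx], v[idx], grid, span)
            s0 = _smooth_arm(y0[idx], v[idx], grid, span)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where((s1 > 0) & (s0 > 0), np.log(s1 / s0), np.nan)
        return out

    est = curve(np.arange(n))
    est[sparse] = np.nan

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, n_grid))
    for b in range(n_boot):
        boot[b] = curve(rng.integers(n, size=n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(boot, 2.5, axis=0)
        hi = np.nanpercentile(boot, 97.5, axis=0)
    # the band is the percentile interval united with the point estimate
    lo = np.fmin(lo, est)
    hi = np.fmax(hi, est)
    lo[sparse] = np.nan
    hi[sparse] = np.nan
    return CateCurve(
        covariate_grid=grid,
        estimate=est,
        ci_lower=lo,
        ci_upper=hi,
        span=span,
        n_boot=n_boot,
    )
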