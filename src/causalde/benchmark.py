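"""Benchmark metrics and replicated-simulation harness.

Four metrics score one pipeline run against the generator's ground truth:

- FPR / TPR of the causal DE test at a nominal p-value level (default 0.1);
- ARI between k-means clusters of the estimated confounder scores Uhat and
  the true latent group labels;
- ASW (average silhouette width, rescaled to [0, 1]) of the true groups in
  the estimated counterfactual control matrix Yhat(0), computed on the
  top-20 principal components of its log1p transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .containers import GeneEffectTable
from .simulate import SimConfig, SimTruth, simulate_pseudobulk

logger = logging.getLogger(__name__)

__all__ = ["compute_fpr_tpr", "compute_ari", "compute_asw", "run_benchmark"]


def compute_fpr_tpr(
    table: GeneEffectTable,
    truth: SimTruth,
    level: float = 0.1,
    use_q: bool = False,
) -> tuple[float, float]:
    """False/true positive rates of the per-gene test at a nominal level.

    Uses raw p-values by default (q-values with ``use_q=True``); genes with
    NaN p never count as rejections. Rates are NaN when the corresponding
    gene set is empty.
    """
    stat = table.table["q" if use_q else "p"].to_numpy()
    if len(stat) != len(truth.de_mask):
        raise ValueError("result table and truth disagree on gene count")
    rejected = np.nan_to_num(stat, nan=np.inf) < level
    n_null = int((~truth.de_mask).sum())
    n_de = int(truth.de_mask.sum())
    fpr = float(rejected[~truth.de_mask].sum() / n_null) if n_null else np.nan
    tpr = float(rejected[truth.de_mask].sum() / n_de) if n_de else np.nan
    return fpr, tpr


def compute_ari(U_hat: np.ndarray, truth: SimTruth, random_state: int = 0) -> float:
    """ARI between k-means clusters of Uhat (k = true group count) and truth."""
    U_hat = np.atleast_2d(np.asarray(U_hat, dtype=float))
    if U_hat.shape[1] < 1:
        raise ValueError("U_hat needs at least one column")
    k = int(len(np.unique(truth.group_labels)))
    if k > U_hat.shape[0]:
        raise ValueError("more groups than observations")
    km = KMeans(n_clusters=k, n_init=10, random_state=random_state)
    labels = km.fit_predict(U_hat)
    return float(adjusted_rand_score(truth.group_labels, labels))


def compute_asw(
    response: np.ndarray,
    truth: SimTruth,
    n_components: int = 20,
    log_transform: bool = True,
) -> float:
    """Rescaled mean silhouette width of true groups in a response matrix.

    The response (typically the imputed control matrix Yhat(0)) is log1p
    transformed, projected on its top principal components, and scored with
    Euclidean silhouettes against the true group labels; the result is
    mapped from [-1, 1] to [0, 1] via (s + 1) / 2. Singleton groups are
    excluded with a warning.
    """
    response = np.asarray(response, dtype=float)
    labels = np.asarray(truth.group_labels)
    uniq, counts = np.unique(labels, return_counts=True)
    keep_groups = uniq[counts >= 2]
    if len(keep_groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 members")
    if len(keep_groups) < len(uniq):
        warnings.warn("singleton groups excluded from ASW", stacklevel=2)
    keep = np.isin(labels, keep_groups)
    Xr = response[keep]
    if log_transform:
        Xr = np.log1p(np.clip(Xr, 0.0, None))
    k = min(n_components, min(Xr.shape) - 1)
    emb = PCA(n_components=k, random_state=0).fit_transform(Xr)
    s = silhouette_score(emb, labels[keep], metric="euclidean")
    return float((s + 1.0) / 2.0)


def run_benchmark(
    cfg_grid: Sequence[SimConfig],
    n_reps: int = 1,
    level: float = 0.1,
    rank: Optional[int] = None,
    rank_grid: Optional[Sequence[int]] = None,
    pipeline_opts: Optional[dict] = None,
) -> pd.DataFrame:
    """Simulate, run the full pipeline and score, per config x replicate.

    ``rank`` fixes the fitted latent dimension (defaults to each config's
    ``r_true``); ``rank_grid`` switches to JIC rank selection. Returns a tidy
    frame with columns (config, rep, seed, metric, value); pipeline failures
    yield NaN rows instead of aborting the sweep.
    """
    from .pipeline import PipelineConfig, run_pipeline  # local import: avoid cycle

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for ci, cfg in enumerate(cfg_grid):
        for rep in range(n_reps):
            seed = int(cfg.seed + rep)
            sim_cfg = replace(cfg, seed=seed)
            metrics = {m: np.nan for m in ("fpr", "tpr", "ari", "asw")}
            try:
                cm, design, truth = simulate_pseudobulk(sim_cfg)
                pcfg = PipelineConfig(**(pipeline_opts or {}))
                pcfg.factor.rank = int(rank if rank is not None else cfg.r_true)
                pcfg.factor.rank_grid = list(rank_grid) if rank_grid else None
                result = run_pipeline(cm, design, pcfg)
                fpr, tpr = compute_fpr_tpr(result.table, truth, level=level)
                metrics["fpr"], metrics["tpr"] = fpr, tpr
                if result.factor_fit.rank > 0:
                    metrics["ari"] = compute_ari(result.factor_fit.U_causal, truth)
                metrics["asw"] = compute_asw(
                    result.potential_outcomes.y0_hat, truth
                )
            except Exception:  # noqa: BLE001
                logger.exception("pipeline failed for config %d rep %d", ci, rep)
            for name, value in metrics.items():
                rows.append(
                    {"config": ci, "rep": rep, "seed": seed, "metric": name, "value": value}
                )
    return pd.DataFrame(rows)
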