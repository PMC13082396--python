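"""Reading and writing counts, designs and result tables; pseudo-bulk
aggregation; size-factor estimation.

Supported on-disk formats are Matrix Market (.mtx) with barcode/feature
sidecar files, and delimited text (TSV/CSV) with a header row and the first
column holding observation identifiers. Results are written as TSV with a
fixed column order.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import RESULT_COLUMNS, CountMatrix, GeneEffectTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts",
    "write_counts",
    "estimate_size_factors",
    "pseudobulk_aggregate",
    "write_results",
    "read_results",
]

# median-of-ratios needs a stable geometric-mean reference; with fewer
# all-positive genes than this the classic estimator is degenerate
MIN_REFERENCE_GENES = 50


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts(
    path,
    fmt: Optional[str] = None,
    transpose: bool = False,
) -> CountMatrix:
    """Read a count matrix from MTX or delimited text.

    For MTX, sidecar identifier files ``<stem>_barcodes.tsv`` /
    ``<stem>_features.tsv`` (or ``barcodes.tsv`` / ``features.tsv`` in the
    same directory) provide observation and gene ids. Orientation is
    observations x genes; pass ``transpose=True`` for genes x observations
    inputs (never guessed).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv", ".txt": "tsv"}.get(
            path.suffix.lower()
        )
        if fmt is None:
            raise ValueError(f"cannot infer format from extension: {path.name}")
    if fmt == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"malformed Matrix Market file {path}: {exc}") from exc
        Y = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        if transpose:
            Y = Y.T
        obs_ids, gene_ids = _read_mtx_sidecars(path, Y.shape)
        return CountMatrix(Y, obs_ids=obs_ids, gene_ids=gene_ids)
    if fmt in ("tsv", "csv"):
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"malformed {fmt.upper()} file {path}: {exc}") from exc
        Y = df.to_numpy(dtype=float)
        obs_ids, gene_ids = df.index.to_numpy(object), df.columns.to_numpy(object)
        if transpose:
            Y, obs_ids, gene_ids = Y.T, gene_ids, obs_ids
        return CountMatrix(Y, obs_ids=obs_ids, gene_ids=gene_ids)
    raise ValueError(f"unknown format {fmt!r}; expected one of mtx, tsv, csv")


def _read_mtx_sidecars(path: Path, shape: Tuple[int, int]):
    n, p = shape
    stem = path.with_suffix("")
    candidates = [
        (Path(f"{stem}_barcodes.tsv"), Path(f"{stem}_features.tsv")),
        (path.parent / "barcodes.tsv", path.parent / "features.tsv"),
    ]
    for bpath, fpath in candidates:
        if bpath.exists() and fpath.exists():
            obs = pd.read_csv(bpath, sep="\t", header=None)[0].to_numpy(object)
            gene = pd.read_csv(fpath, sep="\t", header=None)[0].to_numpy(object)
            if len(obs) != n or len(gene) != p:
                raise ValueError(
                    f"sidecar identifier counts ({len(obs)}, {len(gene)}) do not "
                    f"match matrix dimensions ({n}, {p})"
                )
            return obs, gene
    return None, None


def write_counts(cm: CountMatrix, path) -> None:
    """Write counts as delimited text (delimiter chosen by extension)."""
    path = Path(path)
    df = pd.DataFrame(cm.counts, index=cm.obs_ids, columns=cm.gene_ids)
    df.to_csv(path, sep=_delimiter_for(path))


def estimate_size_factors(
    cm: CountMatrix, method: str = "median_of_ratios"
) -> np.ndarray:
    """Estimate per-observation size factors, normalized to mean 1.

    ``median_of_ratios`` is the classic geometric-mean-reference estimator
    restricted to genes with all-positive counts; when fewer than 50 such
    genes exist it falls back to ``library_size`` with a warning (sparse
    single-cell data routinely degenerates the reference). The estimate is
    stored on ``cm.size_factors``.
    """
    Y = cm.counts.astype(float)
    totals = Y.sum(axis=1)
    if np.any(totals <= 0):
        bad = np.asarray(cm.obs_ids)[totals <= 0].tolist()
        raise ValueError(f"observations with all-zero counts: {bad}")
    if method == "median_of_ratios":
        positive = np.all(Y > 0, axis=0)
        if positive.sum() >= MIN_REFERENCE_GENES:
            ref = np.exp(np.mean(np.log(Y[:, positive]), axis=0))
            s = np.median(Y[:, positive] / ref, axis=1)
        else:
            # sparse data: poscounts-style reference over genes that are
            # nonzero in at least half the cells; per-cell median ratio over
            # that cell's nonzero reference genes. Library size is NOT a safe
            # fallback here -- it is post-treatment and leaks DE signal into
            # the adjusted scale of every null gene.
            detected = (Y > 0).mean(axis=0) >= 0.5
            if detected.sum() < MIN_REFERENCE_GENES:
                warnings.warn(
                    f"only {int(detected.sum())} genes detected in >= 50% of "
                    "observations; falling back to library_size size factors",
                    stacklevel=2,
                )
                method = "library_size"
            else:
                sub = Y[:, detected]
                with np.errstate(divide="ignore"):
                    logs = np.where(sub > 0, np.log(sub), np.nan)
                ref = np.exp(np.nanmean(logs, axis=0))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    ratios = np.where(sub > 0, sub / ref, np.nan)
                    s = np.nanmedian(ratios, axis=1)
                if np.any(~np.isfinite(s)) or np.any(s <= 0):
                    warnings.warn(
                        "degenerate poscounts reference for some observations; "
                        "falling back to library_size size factors",
                        stacklevel=2,
                    )
                    method = "library_size"
    if method == "library_size":
        s = totals
    elif method != "median_of_ratios":
        raise ValueError(f"unknown size-factor method {method!r}")
    s = np.asarray(s, dtype=float)
    s = s / s.mean()
    cm.size_factors = s
    return s


def pseudobulk_aggregate(
    cell_counts: CountMatrix,
    sample_labels: Sequence,
    celltype_labels: Sequence,
    celltype,
) -> CountMatrix:
    """Sum single-cell counts into per-sample pseudo-bulk rows for one cell type.

    Modeling proceeds one cell type at a time: pooled fits let latent factors
    absorb marker-gene structure instead of the within-type variation that
    actually confounds treatment. Samples contributing zero cells of the
    requested type are dropped and reported via a warning.
    """
    sample_labels = np.asarray(sample_labels, dtype=object)
    celltype_labels = np.asarray(celltype_labels, dtype=object)
    n = cell_counts.n_obs
    if len(sample_labels) != n or len(celltype_labels) != n:
        raise ValueError("labels must align with the rows of cell_counts")
    available = set(celltype_labels.tolist())
    if celltype not in available:
        raise ValueError(
            f"cell type {celltype!r} not present; available: {sorted(map(str, available))}"
        )
    mask = celltype_labels == celltype
    all_samples = pd.unique(sample_labels)
    kept_rows, kept_samples, dropped = [], [], []
    for sample in all_samples:
        sel = mask & (sample_labels == sample)
        if not sel.any():
            dropped.append(sample)
            continue
        kept_rows.append(cell_counts.counts[sel].sum(axis=0))
        kept_samples.append(sample)
    if dropped:
        warnings.warn(
            f"samples with zero {celltype!r} cells dropped: {dropped}", stacklevel=2
        )
    return CountMatrix(
        np.asarray(kept_rows),
        obs_ids=np.asarray(kept_samples, dtype=object),
        gene_ids=cell_counts.gene_ids,
    )


def write_results(table: GeneEffectTable, path) -> None:
    """Write a GeneEffectTable as TSV (fixed column order, 12 sig. digits)."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    df = table.table.copy()
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.12g")


def read_results(path) -> GeneEffectTable:
    df = pd.read_csv(Path(path), sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"result file missing columns {missing}")
    return GeneEffectTable(df)
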