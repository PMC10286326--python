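"""Cell-level quality control and CP10K log-normalization.

Cells are filtered on two per-cell metrics: the number of detected genes
(genes with count > 0) and the mitochondrial count fraction. The exclusion
rule is strict — a cell is removed iff it has *fewer than* ``min_genes``
detected genes or a mito fraction *greater than* ``max_mito`` — so cells
sitting exactly on either threshold are retained.

Normalization is counts-per-10k with a natural log1p transform:
``ln(1 + 1e4 * count / cell_total)``. The convention is recorded in
``uns['normalization']`` so downstream outputs can audit it.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .errors import InputError

log = logging.getLogger(__name__)


def _row_sums(X) -> np.ndarray:
    if sparse.issparse(X):
        return np.asarray(X.sum(axis=1)).ravel()
    return np.asarray(X).sum(axis=1)


def compute_qc_metrics(adata: ad.AnnData, mito_col: str = "is_mito") -> pd.DataFrame:
    """Per-cell QC metrics: ``n_detected``, ``total_counts``, ``mito_fraction``.

    The mito fraction of an all-zero cell is defined as 0 (such a cell is
    removed by the detected-genes filter anyway). If the ``is_mito`` column
    is absent from ``adata.var`` no gene is treated as mitochondrial.
    """
    X = adata.X
    if sparse.issparse(X):
        n_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        n_detected = (np.asarray(X) > 0).sum(axis=1)
    total = _row_sums(X)
    if mito_col in adata.var.columns:
        mito_mask = np.asarray(adata.var[mito_col], dtype=bool)
    else:
        mito_mask = np.zeros(adata.n_vars, dtype=bool)
    if mito_mask.any():
        mito_counts = _row_sums(X[:, mito_mask])
    else:
        mito_counts = np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(total > 0, mito_counts / np.where(total > 0, total, 1), 0.0)
    return pd.DataFrame(
        {
            "n_detected": np.asarray(n_detected, dtype=int),
            "total_counts": total,
            "mito_fraction": mito_fraction,
        },
        index=adata.obs_names,
    )


def filter_cells(
    metrics: pd.DataFrame, min_genes: int = 600, max_mito: float = 0.15
) -> np.ndarray:
    """Boolean keep-mask: kept iff ``n_detected >= min_genes`` and ``mito_fraction <= max_mito``.

    Thresholds themselves are retained (the exclusion is strictly
    "fewer than"/"greater than"). An empty result is allowed and logged.
    """
    if min_genes < 0 or max_mito < 0:
        raise InputError("QC thresholds must be non-negative")
    keep = (metrics["n_detected"].to_numpy() >= min_genes) & (
        metrics["mito_fraction"].to_numpy() <= max_mito
    )
    n_removed = int((~keep).sum())
    log.info(
        "QC: %d cells in, %d kept, %d removed (min_genes=%s, max_mito=%s)",
        len(keep), int(keep.sum()), n_removed, min_genes, max_mito,
    )
    if not keep.any():
        log.warning("QC removed every cell")
    return keep


def apply_qc(
    adata: ad.AnnData,
    min_genes: int = 600,
    max_mito: float = 0.15,
    prune_genes: bool = True,
) -> ad.AnnData:
    """Filter cells by QC and optionally prune genes detected in zero retained cells."""
    metrics = compute_qc_metrics(adata)
    keep = filter_cells(metrics, min_genes=min_genes, max_mito=max_mito)
    out = adata[keep].copy()
    out.obs = out.obs.join(metrics.loc[keep])
    if prune_genes and out.n_obs > 0:
        X = out.X
        expressed = (
            np.asarray((X > 0).sum(axis=0)).ravel() if sparse.issparse(X) else (np.asarray(X) > 0).sum(axis=0)
        ) > 0
        n_pruned = int((~expressed).sum())
        if n_pruned:
            log.info("pruning %d genes expressed in zero retained cells", n_pruned)
            out = out[:, expressed].copy()
    return out


def normalize_cp10k(adata: ad.AnnData, layer: str = "lognorm") -> ad.AnnData:
    """Add a ``ln(1 + 1e4 * count / cell_total)`` layer; zero counts stay zero.

    Raises :class:`InputError` on any cell with zero total counts — those
    must be removed by QC first.
    """
    total = _row_sums(adata.X)
    if (total <= 0).any():
        bad = np.flatnonzero(total <= 0)
        raise InputError(
            f"{len(bad)} cell(s) have zero total counts (e.g. {adata.obs_names[bad[0]]}); run QC first"
        )
    X = adata.X
    if sparse.issparse(X):
        norm = X.tocsr(copy=True).astype(float)
        norm.data = norm.data * np.repeat(1e4 / total, np.diff(norm.indptr))
        norm.data = np.log1p(norm.data)
    else:
        norm = np.log1p(1e4 * np.asarray(X, dtype=float) / total[:, None])
    out = adata.copy()
    out.layers[layer] = norm
    out.uns["normalization"] = {"scale_factor": 1e4, "log": "ln1p", "layer": layer}
    return out
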