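"""Per-cluster two-group Wilcoxon differential expression.

The marker test is the two-sided Wilcoxon rank-sum test on the
log-normalized values, with the log2 fold change computed on exponentiated
means plus a pseudocount of one:

    log2fc = log2( (mean_A(e^v - 1) + 1) / (mean_B(e^v - 1) + 1) )

For small samples (n + m <= 14) an exact test is available that enumerates
every C(n+m, n) assignment of the pooled average ranks — valid under ties,
and the reference for the normal approximation, which uses average ranks,
tie-corrected variance and a continuity correction.

DEG sets use strict thresholds (|log2fc| > lfc_cut and p < p_cut), and a
comparison is only attempted for cell types with at least ``min_cells``
cells in both groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

EXACT_MAX_N = 14


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum statistic of x, p).

    ``mode='exact'`` enumerates all rank partitions (feasible for
    n + m <= 14; correct under ties since it permutes the observed average
    ranks). ``mode='approx'`` uses the normal approximation with average
    ranks, tie-corrected variance and continuity correction. ``'auto'``
    selects exact when n + m <= 14. All-tied input returns p = 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise InputError("wilcoxon_rank_sum requires two non-empty samples")
    n, m = x.size, y.size
    N = n + m
    if mode == "auto":
        mode = "exact" if N <= EXACT_MAX_N else "approx"
    if mode not in ("exact", "approx"):
        raise InputError(f"unknown mode {mode!r}")

    ranks = stats.rankdata(np.concatenate([x, y]))
    W = float(ranks[:n].sum())
    mu = n * (N + 1) / 2.0

    if np.ptp(np.concatenate([x, y])) == 0:  # every value tied
        return W, 1.0

    if mode == "exact":
        dev = abs(W - mu)
        total = comb(N, n)
        hits = 0
        for idx in combinations(range(N), n):
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
                hits += 1
        return W, hits / total

    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if sigma2 <= 0:
        return W, 1.0
    d = W - mu
    z = (d - 0.5 * np.sign(d)) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return W, float(p)


def _wilcoxon_approx_matrix(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    """Vectorized approx-mode two-sided p over columns (genes)."""
    na, nb = Xa.shape[0], Xb.shape[0]
    N = na + nb
    Z = np.vstack([Xa, Xb])
    R = stats.rankdata(Z, axis=0)
    W = R[:na].sum(axis=0)
    mu = na * (N + 1) / 2.0

    tie_term = np.empty(Z.shape[1])
    for j in range(Z.shape[1]):
        _, counts = np.unique(Z[:, j], return_counts=True)
        tie_term[j] = ((counts**3) - counts).sum()
    sigma2 = na * nb / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    d = W - mu
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (d - 0.5 * np.sign(d)) / np.sqrt(sigma2)
    p = np.where(sigma2 > 0, np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z))), 1.0)
    return p


def log2_fold_change(norm_a, norm_b) -> float:
    """log2 of exponentiated-mean-plus-one ratio of two normalized samples."""
    a = np.asarray(norm_a, dtype=float)
    b = np.asarray(norm_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("log2_fold_change requires two non-empty samples")
    return float(np.log2((np.expm1(a).mean() + 1.0) / (np.expm1(b).mean() + 1.0)))


def comparable_celltypes(
    ann: pd.DataFrame,
    group_a: str,
    group_b: str,
    min_cells: int = 3,
    group_key: str = "group",
    cluster_key: str = "cluster",
) -> list[str]:
    """Cell types with at least ``min_cells`` cells in both groups."""
    if ann.empty:
        raise InputError("annotation is empty")
    counts = (
        ann[ann[group_key].isin([group_a, group_b])]
        .groupby([cluster_key, group_key], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    out = []
    for ct in counts.index:
        ca = int(counts.loc[ct, group_a]) if group_a in counts.columns else 0
        cb = int(counts.loc[ct, group_b]) if group_b in counts.columns else 0
        if ca >= min_cells and cb >= min_cells:
            out.append(str(ct))
    return sorted(out)


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def find_markers(
    adata: ad.AnnData,
    cell_type: str,
    group_a: str,
    group_b: str,
    *,
    layer: str = "lognorm",
    min_pct: float = 0.1,
    min_cells: int = 3,
    group_key: str = "group",
    cluster_key: str = "cluster",
) -> pd.DataFrame:
    """Wilcoxon DE table (group_a vs group_b) for one cell type.

    One row per gene expressed (at fraction >= ``min_pct``) in at least one
    of the groups, with columns gene, log2fc, p, p_adj (BH over the tested
    genes), pct_a, pct_b. Raises :class:`InputError` when either group has
    fewer than ``min_cells`` cells of the cell type — the paper-style
    three-cell comparison filter.
    """
    obs = adata.obs
    in_ct = obs[cluster_key].astype(str) == str(cell_type)
    mask_a = in_ct & (obs[group_key].astype(str) == str(group_a))
    mask_b = in_ct & (obs[group_key].astype(str) == str(group_b))
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if na < min_cells or nb < min_cells:
        raise InputError(
            f"cell type {cell_type!r} has {na} vs {nb} cells in {group_a!r}/{group_b!r}; "
            f"the minimum-{min_cells}-cells-per-group comparison filter excludes it"
        )
    if layer not in adata.layers:
        raise InputError(f"layer {layer!r} not found; run normalize_cp10k first")
    Xa = _dense(adata.layers[layer][np.asarray(mask_a)])
    Xb = _dense(adata.layers[layer][np.asarray(mask_b)])

    pct_a = (Xa > 0).mean(axis=0)
    pct_b = (Xb > 0).mean(axis=0)
    max_pct = np.maximum(pct_a, pct_b)
    keep = (max_pct >= min_pct) & (max_pct > 0)
    genes = np.asarray(adata.var_names)[keep]
    Xa, Xb = Xa[:, keep], Xb[:, keep]

    p = _wilcoxon_approx_matrix(Xa, Xb)
    lfc = np.log2((np.expm1(Xa).mean(axis=0) + 1.0) / (np.expm1(Xb).mean(axis=0) + 1.0))
    p_adj = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])

    table = pd.DataFrame(
        {
            "gene": genes,
            "log2fc": lfc,
            "p": p,
            "p_adj": p_adj,
            "pct_a": pct_a[keep],
            "pct_b": pct_b[keep],
        }
    )
    table = table.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)
    table.attrs["contrast"] = f"{group_a}:{group_b}"
    table.attrs["cell_type"] = str(cell_type)
    table.attrs["log_base"] = 2
    return table


@dataclass(frozen=True)
class DEGSet:
    """Directional thresholded DEG sets for one (contrast, cell type)."""

    contrast: str
    cell_type: str
    up: frozenset[str]
    down: frozenset[str]
    lfc_cut: float = 0.25
    p_cut: float = 0.05

    def __post_init__(self):
        if self.up & self.down:
            raise InputError("up and down DEG sets must be disjoint")


def threshold_degs(
    table: pd.DataFrame,
    lfc_cut: float = 0.25,
    p_cut: float = 0.05,
    contrast: str | None = None,
    cell_type: str | None = None,
) -> DEGSet:
    """Strict-inequality thresholding of a marker table into a DEGSet.

    ``up`` holds genes with log2fc > lfc_cut and p < p_cut; ``down`` the
    mirror. Values exactly at a threshold are excluded.
    """
    sig = table["p"].to_numpy() < p_cut
    up = frozenset(table.loc[sig & (table["log2fc"].to_numpy() > lfc_cut), "gene"])
    down = frozenset(table.loc[sig & (table["log2fc"].to_numpy() < -lfc_cut), "gene"])
    return DEGSet(
        contrast=contrast or table.attrs.get("contrast", ""),
        cell_type=cell_type or table.attrs.get("cell_type", ""),
        up=up,
        down=down,
        lfc_cut=lfc_cut,
        p_cut=p_cut,
    )
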