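"""Spearman correlation of gene pairs and threshold screening of correlates.

rho is the product-moment correlation of average ranks. The two-sided p
uses the t-distribution approximation, t = rho * sqrt((n-2)/(1-rho^2)),
for n > 9, and an exact enumeration over all n! permutations of one rank
vector for n <= 9 (valid under ties, since tied values keep their average
ranks). The screen keeps candidates with rho strictly above a positive
threshold and p strictly below a cut — a one-sided, positive-correlation
screen by default, with the focal gene itself excluded.
"""

from __future__ import annotations

from itertools import permutations
from math import factorial

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .errors import InputError

EXACT_MAX_N = 9
_TINY = np.finfo(float).tiny


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        return np.nan
    return float((rxc * ryc).sum() / denom)


def _p_approx(rho: float, n: int) -> float:
    # continuity correction: half the no-ties rho lattice step, 12/(n(n^2-1)),
    # aligns the t tail with the >= convention of the permutation null
    r = max(0.0, abs(rho) - 6.0 / (n * (n * n - 1)))
    if r >= 1.0:
        return _TINY
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return float(min(1.0, 2.0 * stats.t.sf(t, df=n - 2)))


def spearman(x, y, mode: str = "auto") -> tuple[float, float]:
    """Spearman rho and two-sided p for two equal-length vectors (n >= 4).

    ``mode`` is ``'exact'`` (permutation enumeration, n <= 9), ``'approx'``
    (t approximation) or ``'auto'``. All-constant input yields (nan, nan) —
    the correlation is undefined and reported missing.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise InputError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 4:
        raise InputError(f"spearman needs n >= 4, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    if mode == "auto":
        mode = "exact" if n <= EXACT_MAX_N else "approx"
    if mode not in ("exact", "approx"):
        raise InputError(f"unknown mode {mode!r}")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rho_of_ranks(rx, ry)

    if mode == "approx":
        return rho, _p_approx(rho, n)
    if mode == "exact" and n > EXACT_MAX_N:
        raise InputError(f"exact mode enumerates n! permutations; limited to n <= {EXACT_MAX_N}")

    # enumerate rho over every permutation of one rank vector
    P = np.array(list(permutations(ry)), dtype=float)
    rxc = rx - rx.mean()
    Pc = P - P.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc**2).sum() * (Pc**2).sum(axis=1))
    rhos = (Pc @ rxc) / denom
    p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    assert len(rhos) == factorial(n)
    return rho, p


def spearman_matrix(
    adata: ad.AnnData,
    genes,
    cells=None,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Pairwise Spearman rho matrix over a gene list (for heatmap-style output)."""
    X = _gene_matrix(adata, genes, cells, layer)
    R = stats.rankdata(X, axis=0)
    Rc = R - R.mean(axis=0)
    norms = np.sqrt((Rc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (Rc.T @ Rc) / np.outer(norms, norms)
    rho[:, norms == 0] = np.nan
    rho[norms == 0, :] = np.nan
    return pd.DataFrame(rho, index=list(genes), columns=list(genes))


def _gene_matrix(adata, genes, cells, layer) -> np.ndarray:
    genes = list(genes)
    missing = [g for g in genes if g not in set(adata.var_names)]
    if missing:
        raise InputError(f"genes absent from the matrix: {missing[:5]}")
    sub = adata if cells is None else adata[cells]
    if layer not in adata.layers:
        raise InputError(f"layer {layer!r} not found; run normalize_cp10k first")
    idx = pd.Index(adata.var_names).get_indexer(genes)
    X = sub.layers[layer][:, idx]
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def screen_correlates(
    adata: ad.AnnData,
    focal_gene: str,
    candidates=None,
    cells=None,
    r_cut: float = 0.15,
    p_cut: float = 0.01,
    layer: str = "lognorm",
    use_abs: bool = False,
) -> pd.DataFrame:
    """Screen candidate genes correlated with a focal gene over a cell subset.

    Keeps candidates with rho > ``r_cut`` (or |rho| > r_cut when
    ``use_abs``) and p < ``p_cut``, both strict; the focal gene itself is
    excluded. Returns a DataFrame (gene, rho, p, n) sorted by descending
    rho. Requires >= 10 cells so the t-approximation p is applicable.
    """
    if focal_gene not in set(adata.var_names):
        raise InputError(f"focal gene {focal_gene!r} absent from the matrix")
    if candidates is None:
        candidates = [g for g in adata.var_names if g != focal_gene]
    candidates = [g for g in dict.fromkeys(candidates) if g != focal_gene]
    X = _gene_matrix(adata, [focal_gene] + candidates, cells, layer)
    n = X.shape[0]
    if n < 10:
        raise InputError(f"screen needs >= 10 cells, got {n}")
    R = stats.rankdata(X, axis=0)
    Rc = R - R.mean(axis=0)
    norms = np.sqrt((Rc**2).sum(axis=0))
    focal = Rc[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (Rc[:, 1:].T @ focal) / (norms[1:] * norms[0])
    if norms[0] == 0:
        raise InputError(f"focal gene {focal_gene!r} is constant over the chosen cells")
    rho = np.where(norms[1:] == 0, np.nan, rho)
    p = np.array([_p_approx(r, n) if np.isfinite(r) else np.nan for r in rho])
    table = pd.DataFrame({"gene": candidates, "rho": rho, "p": p, "n": n})
    stat = np.abs(table["rho"]) if use_abs else table["rho"]
    keep = (stat > r_cut) & (table["p"] < p_cut)
    out = table[keep.fillna(False)].sort_values(
        ["rho", "gene"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)
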