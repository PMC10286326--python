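"""Regulon rescue-target extraction and binned-control gene-set scoring.

A regulon table lists (TF, target, importance) rows in the dialect produced
by co-expression network inference tools. The "rescue target genes" of a TF
are the intersection of its predicted targets with a cluster's down-rescue
genes, ranked by importance (descending, ties broken lexicographically) and
truncated to the top n.

Gene sets are scored per cell against expression-matched controls: each set
gene contributes up to ``n_ctrl`` control genes sampled (seeded, without
replacement) from its average-expression bin among ``n_bins``
equal-frequency bins of all genes, and the score is the mean normalized
expression over the set minus the mean over the pooled controls. Because
sampling is capped at the bin occupancy, scoring the all-genes set pools
every gene as its own control and returns exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .de import wilcoxon_rank_sum
from .errors import FormatError, InputError

log = logging.getLogger(__name__)

REGULON_COLUMNS = ("TF", "target", "importance")


def read_regulon_table(path) -> pd.DataFrame:
    """Read and validate a TSV of (TF, target, importance) rows.

    Duplicate (TF, target) pairs are collapsed keeping the maximum
    importance, with a warning. Missing columns or negative importances are
    format errors.
    """
    table = pd.read_csv(path, sep="\t", comment="#")
    for col in REGULON_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"regulon table {path} is missing column {col!r}")
    table = table.loc[:, list(REGULON_COLUMNS)].copy()
    table["importance"] = pd.to_numeric(table["importance"], errors="coerce")
    if table["importance"].isna().any():
        raise FormatError(f"regulon table {path} has non-numeric importance values")
    if (table["importance"] < 0).any():
        raise FormatError(f"regulon table {path} has negative importance values")
    n_dup = int(table.duplicated(subset=["TF", "target"]).sum())
    if n_dup:
        log.warning("collapsing %d duplicate (TF, target) rows, keeping max importance", n_dup)
        table = (
            table.groupby(["TF", "target"], as_index=False, sort=False)["importance"].max()
        )
    return table.reset_index(drop=True)


def rescue_target_genes(
    regulons: pd.DataFrame, tf: str, rescue_down: frozenset[str] | set[str], top_n: int = 20
) -> list[str]:
    """Targets of ``tf`` intersected with ``rescue_down``, ranked by importance.

    Descending importance, ties lexicographic, truncated to ``top_n``. An
    empty intersection returns an empty list; an unknown TF is an error.
    """
    rows = regulons[regulons["TF"] == tf]
    if rows.empty:
        raise InputError(f"TF {tf!r} not present in the regulon table")
    hits = rows[rows["target"].isin(rescue_down)]
    ranked = hits.sort_values(
        ["importance", "target"], ascending=[False, True], kind="mergesort"
    )
    return [str(g) for g in ranked["target"].head(top_n)]


@dataclass
class ModuleScores:
    """Per-cell gene-set scores plus the scoring metadata."""

    scores: pd.Series
    gene_set_id: str
    n_bins: int
    n_ctrl: int
    seed: int
    control_genes: frozenset[str] = field(default_factory=frozenset, repr=False)


def module_score(
    adata: ad.AnnData,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    layer: str = "lognorm",
    gene_set_id: str = "gene_set",
) -> ModuleScores:
    """Binned-control module score per cell.

    For each set gene, ``min(n_ctrl, bin size)`` control genes are sampled
    without replacement from its average-expression bin; the per-cell score
    is the mean over set genes minus the mean over the pooled controls.
    Deterministic given the seed. Genes absent from the matrix are dropped;
    a fully absent set is an error listing the missing genes.
    """
    gene_set = sorted(set(gene_set))
    present = [g for g in gene_set if g in set(adata.var_names)]
    if not present:
        raise InputError(f"gene set entirely absent from the matrix: {sorted(gene_set)}")
    missing = sorted(set(gene_set) - set(present))
    if missing:
        log.warning("%d gene(s) of %s absent from the matrix", len(missing), gene_set_id)

    if layer not in adata.layers:
        raise InputError(f"layer {layer!r} not found; run normalize_cp10k first")
    X = adata.layers[layer]
    mean_expr = (
        np.asarray(X.mean(axis=0)).ravel() if sparse.issparse(X) else np.asarray(X).mean(axis=0)
    )
    # equal-frequency bins of all genes by average expression
    order_rank = pd.Series(mean_expr, index=adata.var_names).rank(method="first")
    bins = pd.qcut(order_rank, q=min(n_bins, adata.n_vars), labels=False)

    rng = np.random.default_rng(seed)
    bin_members = {b: np.asarray(idx) for b, idx in bins.groupby(bins).groups.items()}
    ctrl: set[str] = set()
    for g in present:  # sorted -> deterministic sampling order
        members = bin_members[bins[g]]
        k = min(n_ctrl, len(members))
        ctrl.update(rng.choice(members, size=k, replace=False))

    var_index = pd.Index(adata.var_names)
    set_idx = var_index.get_indexer(present)
    ctrl_idx = var_index.get_indexer(sorted(ctrl))
    Xd = X.toarray() if sparse.issparse(X) else np.asarray(X)
    scores = Xd[:, set_idx].mean(axis=1) - Xd[:, ctrl_idx].mean(axis=1)
    return ModuleScores(
        scores=pd.Series(scores, index=adata.obs_names, name="score"),
        gene_set_id=gene_set_id,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
        control_genes=frozenset(ctrl),
    )


def score_group_test(
    scores: ModuleScores,
    ann: pd.DataFrame,
    group_a: str,
    group_b: str,
    group_key: str = "group",
    min_cells: int = 3,
) -> float:
    """Two-sided Wilcoxon rank-sum p comparing module scores between two groups."""
    groups = ann.loc[scores.scores.index, group_key].astype(str)
    a = scores.scores[groups == str(group_a)].to_numpy()
    b = scores.scores[groups == str(group_b)].to_numpy()
    if a.size < min_cells or b.size < min_cells:
        raise InputError(
            f"need >= {min_cells} scored cells per group, got {a.size} vs {b.size}"
        )
    _, p = wilcoxon_rank_sum(a, b, mode="auto")
    return p
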