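"""Hypergeometric over-representation analysis against named gene sets.

For a query of n genes drawn from a universe of N, a set of K genes with k
genes in the overlap is scored with the upper-tail probability
P(X >= k) for X ~ Hypergeometric(N, K, n), with Benjamini-Hochberg q-values
across the collection. The universe is explicit — by default the genes
surviving QC — so results are reproducible, unlike web tools that apply an
implicit background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets harmonized against an explicit universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self):
        harmonized = {}
        for name, genes in self.sets.items():
            inside = frozenset(genes) & self.universe
            dropped = len(genes) - len(inside)
            if dropped:
                log.warning("set %r: %d gene(s) outside the universe dropped", name, dropped)
            harmonized[name] = inside
        object.__setattr__(self, "sets", harmonized)

    def __len__(self) -> int:
        return len(self.sets)


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); k = 0 gives exactly 1."""
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if v < 0:
            raise InputError(f"{name} must be non-negative, got {v}")
    if K > N or n > N:
        raise InputError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise InputError(f"impossible overlap k={k} > min(K={K}, n={n})")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def run_ora(query, collection: GeneSetCollection) -> pd.DataFrame:
    """Over-representation table for a query gene list.

    The query is intersected with the universe first (dropped genes are
    logged); one record per set with columns set, k, K, n, N, p, q (BH over
    the collection), sorted ascending by p with ties broken by set name.
    """
    query = set(query)
    harmonized = query & collection.universe
    dropped = len(query) - len(harmonized)
    if dropped:
        log.info("%d query gene(s) outside the universe dropped", dropped)
    if not harmonized:
        raise InputError("query is empty after intersecting with the universe")

    N = len(collection.universe)
    n = len(harmonized)
    rows = []
    for name in sorted(collection.sets):
        genes = collection.sets[name]
        k = len(genes & harmonized)
        K = len(genes)
        rows.append((name, k, K, n, N, hypergeometric_upper_tail(k, K, n, N)))
    table = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    table = table.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    return table
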