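"""Rescue-DEG derivation and its summary statistics.

A gene is "rescued" when the treatment reverses its disease-induced
dysregulation: a *down-rescue* gene is up in disease-vs-control and down in
treated-vs-disease; an *up-rescue* gene is the mirror. Rescue therefore
requires significance in both contrasts at the stated thresholds, making
each rescue set a subset of the corresponding disease DEG set.

Summary statistics mirror the usual reporting of such analyses: the
per-cell-type ratio of rescue-DEGs to disease DEGs (direction matched), the
frequency with which each gene is rescued across cell types with a top-k
list, and the log2 fold change of cluster composition between groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import DEGSet
from .errors import InputError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RescueSet:
    """Directional rescue gene sets for one cell type."""

    cell_type: str
    down_rescue: frozenset[str]  # up in disease, down after treatment
    up_rescue: frozenset[str]  # down in disease, up after treatment
    thresholds: tuple[float, float] = (0.25, 0.05)


def derive_rescue_degs(eau: DEGSet, prg: DEGSet) -> RescueSet:
    """Directional intersection of the disease and treatment DEG sets.

    ``down_rescue = eau.up ∩ prg.down`` and ``up_rescue = eau.down ∩ prg.up``,
    where ``eau`` is disease-vs-control and ``prg`` treated-vs-disease.
    """
    if eau.cell_type != prg.cell_type:
        raise InputError(
            f"cell type mismatch: {eau.cell_type!r} vs {prg.cell_type!r}"
        )
    rescue = RescueSet(
        cell_type=eau.cell_type,
        down_rescue=frozenset(eau.up & prg.down),
        up_rescue=frozenset(eau.down & prg.up),
        thresholds=(eau.lfc_cut, eau.p_cut),
    )
    assert rescue.down_rescue <= eau.up and rescue.up_rescue <= eau.down
    return rescue


def rescue_ratio(rescue: RescueSet, eau: DEGSet) -> tuple[float, float]:
    """Direction-matched rescue fractions (down_ratio, up_ratio).

    down_ratio = |down_rescue| / |eau.up| and symmetrically; NaN (missing,
    not 0) when the denominator set is empty.
    """
    if rescue.cell_type != eau.cell_type:
        raise InputError(
            f"cell type mismatch: {rescue.cell_type!r} vs {eau.cell_type!r}"
        )
    down = len(rescue.down_rescue) / len(eau.up) if eau.up else math.nan
    up = len(rescue.up_rescue) / len(eau.down) if eau.down else math.nan
    return down, up


def rescue_frequency(
    rescue_sets: dict[str, RescueSet],
    direction: str = "down",
    top_k: int = 15,
) -> tuple[pd.Series, list[str]]:
    """Cross-cell-type rescue frequency per gene, plus the top-k list.

    ``direction`` is ``'down'``, ``'up'`` or ``'both'`` (union per cell
    type). Returns (gene -> number of cell types, top-k genes by frequency
    with lexicographic tie-break).
    """
    if not rescue_sets:
        raise InputError("rescue_frequency needs at least one cell type")
    if direction not in ("down", "up", "both"):
        raise InputError(f"unknown direction {direction!r}")
    counts: dict[str, int] = {}
    for rs in rescue_sets.values():
        if direction == "down":
            genes = rs.down_rescue
        elif direction == "up":
            genes = rs.up_rescue
        else:
            genes = rs.down_rescue | rs.up_rescue
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    freq = pd.Series(counts, dtype=int).sort_index()
    order = sorted(freq.index, key=lambda g: (-freq[g], g))
    return freq, order[:top_k]


def composition_table(
    ann: pd.DataFrame, group_key: str = "group", cluster_key: str = "cluster"
) -> pd.DataFrame:
    """Cluster x group cell counts and within-group proportions (sum to 1)."""
    counts = (
        ann.groupby([cluster_key, group_key], observed=True).size().unstack(fill_value=0)
    )
    props = counts / counts.sum(axis=0)
    out = pd.concat({"count": counts, "proportion": props}, axis=1)
    return out


def proportion_log2fc(
    comp: pd.DataFrame, cluster: str, numerator_group: str, denominator_group: str
) -> float:
    """log2 ratio of a cluster's proportion between two groups; NaN if either is 0."""
    props = comp["proportion"]
    if cluster not in props.index:
        raise InputError(f"unknown cluster {cluster!r}")
    for g in (numerator_group, denominator_group):
        if g not in props.columns:
            raise InputError(f"unknown group {g!r}")
    num = props.loc[cluster, numerator_group]
    den = props.loc[cluster, denominator_group]
    if num == 0 or den == 0:
        log.warning(
            "proportion_log2fc(%s, %s/%s): zero proportion, reporting missing",
            cluster, numerator_group, denominator_group,
        )
        return math.nan
    return float(np.log2(num / den))
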