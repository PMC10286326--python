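"""Synthetic three-condition single-cell count data with planted rescue structure.

The generator emulates the statistical shape of a clustered droplet
scRNA-seq experiment with three biological conditions — a control group
(``naive``), a disease group (``disease``) and a treated disease group
(``treated``) — so that the downstream rescue analysis can be exercised and
validated against a known ground truth without any external download.

Counts are negative binomial around a per-gene log-normal baseline mean,
scaled by a log-normal per-cell size factor. Within each cluster a fraction
of genes is perturbed in the disease group (mean multiplied by
``2**(±disease_log2fc_magnitude)``, sign Bernoulli(1/2) per gene); a
fraction of the perturbed genes is "rescued": their treated-group mean
returns to baseline, while non-rescued perturbed genes keep the disease
mean under treatment. A share of genes is flagged mitochondrial (named with
the ``mt-`` prefix) and carries no group effect, so QC can be tested
without confounding differential expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ConfigurationError

GROUPS = ("naive", "disease", "treated")


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults are the reference study conditions used throughout the test
    suite: 3 clusters x 200 cells per group per cluster x 2000 genes, a 10%
    per-cluster disease effect of magnitude |log2FC| = 1, half of it rescued.
    """

    n_clusters: int = 3
    cells_per_group_per_cluster: int = 200
    n_genes: int = 2000
    mito_gene_fraction: float = 0.05
    baseline_log_mean_mu: float = 0.0
    baseline_log_mean_sigma: float = 1.0
    nb_dispersion: float = 2.0
    libsize_sigma: float = 0.3
    disease_effect_fraction: float = 0.10
    disease_log2fc_magnitude: float = 1.0
    rescue_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_clusters", "cells_per_group_per_cluster", "n_genes"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        for name in ("mito_gene_fraction", "disease_effect_fraction", "rescue_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")
        if self.nb_dispersion <= 0:
            raise ConfigurationError(f"nb_dispersion must be > 0, got {self.nb_dispersion!r}")
        if self.libsize_sigma < 0:
            raise ConfigurationError(f"libsize_sigma must be >= 0, got {self.libsize_sigma!r}")
        if self.disease_log2fc_magnitude <= 0:
            raise ConfigurationError(
                f"disease_log2fc_magnitude must be > 0, got {self.disease_log2fc_magnitude!r}"
            )


@dataclass
class GroundTruth:
    """Planted gene sets recorded by the simulator; the recovery-test oracle.

    Per cluster: ``planted_disease_up``/``planted_disease_down`` are the genes
    whose disease-group mean was shifted up/down, and
    ``planted_rescue_down``/``planted_rescue_up`` are the subsets whose
    treated-group mean returns to baseline (the direction names follow the
    rescue convention: a disease-up gene that comes back down is a
    "down-rescue").
    """

    planted_disease_up: dict[str, frozenset[str]]
    planted_disease_down: dict[str, frozenset[str]]
    planted_rescue_down: dict[str, frozenset[str]]
    planted_rescue_up: dict[str, frozenset[str]]
    genes: tuple[str, ...]
    regulon_membership: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def clusters(self) -> list[str]:
        return sorted(self.planted_disease_up)


def _gene_names(config: SimConfig, rng: np.random.Generator) -> tuple[list[str], np.ndarray]:
    n_mito = int(round(config.mito_gene_fraction * config.n_genes))
    is_mito = np.zeros(config.n_genes, dtype=bool)
    mito_idx = rng.choice(config.n_genes, size=n_mito, replace=False)
    is_mito[mito_idx] = True
    width = max(4, len(str(config.n_genes)))
    names = [
        (f"mt-Gene{i:0{width}d}" if is_mito[i] else f"Gene{i:0{width}d}")
        for i in range(config.n_genes)
    ]
    return names, is_mito


def simulate_counts(
    config: SimConfig, seed: int | None = None
) -> tuple[ad.AnnData, GroundTruth]:
    """Draw a three-condition clustered count matrix plus its ground truth.

    Returns an :class:`~anndata.AnnData` with raw counts in ``.X`` (CSR),
    ``obs['group']`` in {naive, disease, treated}, ``obs['cluster']``, and
    ``var['is_mito']``; and the :class:`GroundTruth` of planted sets.
    Deterministic given ``(config, seed)``; ``seed=None`` uses ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    genes, is_mito = _gene_names(config, rng)
    baseline = rng.lognormal(
        mean=config.baseline_log_mean_mu,
        sigma=config.baseline_log_mean_sigma,
        size=config.n_genes,
    )

    clusters = [f"cluster{c}" for c in range(config.n_clusters)]
    non_mito_idx = np.flatnonzero(~is_mito)
    n_effect = int(round(config.disease_effect_fraction * len(non_mito_idx)))

    up: dict[str, frozenset[str]] = {}
    down: dict[str, frozenset[str]] = {}
    resc_down: dict[str, frozenset[str]] = {}
    resc_up: dict[str, frozenset[str]] = {}
    # per-cluster per-group mean multipliers (genes,) applied on top of baseline
    disease_mult: dict[str, np.ndarray] = {}
    treated_mult: dict[str, np.ndarray] = {}
    for cl in clusters:
        chosen = rng.choice(non_mito_idx, size=n_effect, replace=False)
        signs = rng.random(n_effect) < 0.5  # True -> up
        up_idx = chosen[signs]
        down_idx = chosen[~signs]
        n_resc_up_dir = int(round(config.rescue_fraction * len(up_idx)))
        n_resc_down_dir = int(round(config.rescue_fraction * len(down_idx)))
        rescued_of_up = rng.choice(up_idx, size=n_resc_up_dir, replace=False) if len(up_idx) else np.array([], int)
        rescued_of_down = rng.choice(down_idx, size=n_resc_down_dir, replace=False) if len(down_idx) else np.array([], int)

        fc = 2.0**config.disease_log2fc_magnitude
        d_mult = np.ones(config.n_genes)
        d_mult[up_idx] = fc
        d_mult[down_idx] = 1.0 / fc
        t_mult = d_mult.copy()  # non-rescued genes keep the disease mean
        t_mult[rescued_of_up] = 1.0
        t_mult[rescued_of_down] = 1.0
        disease_mult[cl] = d_mult
        treated_mult[cl] = t_mult

        up[cl] = frozenset(genes[i] for i in up_idx)
        down[cl] = frozenset(genes[i] for i in down_idx)
        resc_down[cl] = frozenset(genes[i] for i in rescued_of_up)
        resc_up[cl] = frozenset(genes[i] for i in rescued_of_down)

    n_cells = config.n_clusters * 3 * config.cells_per_group_per_cluster
    size_factors = rng.lognormal(mean=0.0, sigma=config.libsize_sigma, size=n_cells)

    blocks = []
    obs_group: list[str] = []
    obs_cluster: list[str] = []
    cell0 = 0
    r = config.nb_dispersion
    for cl in clusters:
        for group in GROUPS:
            nc = config.cells_per_group_per_cluster
            if group == "naive":
                mult = np.ones(config.n_genes)
            elif group == "disease":
                mult = disease_mult[cl]
            else:
                mult = treated_mult[cl]
            mean = size_factors[cell0 : cell0 + nc, None] * (baseline * mult)[None, :]
            # NB(mean, shape r) via gamma-Poisson mixture
            lam = rng.gamma(shape=r, scale=mean / r)
            block = rng.poisson(lam)
            blocks.append(block)
            obs_group.extend([group] * nc)
            obs_cluster.extend([cl] * nc)
            cell0 += nc

    counts = np.vstack(blocks)
    width = max(5, len(str(n_cells)))
    cell_ids = [f"cell{i:0{width}d}" for i in range(n_cells)]
    obs = pd.DataFrame(
        {"group": pd.Categorical(obs_group, categories=list(GROUPS)),
         "cluster": pd.Categorical(obs_cluster, categories=clusters)},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    var = pd.DataFrame({"is_mito": is_mito}, index=pd.Index(genes, name="gene_id"))
    adata = ad.AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)
    adata.uns["simulation"] = {"config": vars(config).copy(), "seed": int(config.seed if seed is None else seed)}

    truth = GroundTruth(
        planted_disease_up=up,
        planted_disease_down=down,
        planted_rescue_down=resc_down,
        planted_rescue_up=resc_up,
        genes=tuple(genes),
    )
    return adata, truth


def simulate_regulons(
    truth: GroundTruth,
    n_tfs: int = 10,
    target_overlap: float = 1.0,
    seed: int = 0,
    designated_tf: str = "TF01",
    designated_cluster: str | None = None,
) -> pd.DataFrame:
    """Build a (TF, target, importance) table matched to the planted rescue set.

    The designated TF's target list contains a ``target_overlap`` share of
    the designated cluster's planted down-rescue genes (default: the first
    cluster) plus random extra targets; the remaining TFs get random target
    lists. Importances are positive and reproducible. The membership of each
    TF is recorded in ``truth.regulon_membership``.
    """
    if not isinstance(n_tfs, (int, np.integer)) or n_tfs < 1:
        raise ConfigurationError(f"n_tfs must be >= 1, got {n_tfs!r}")
    if not 0.0 <= target_overlap <= 1.0:
        raise ConfigurationError(f"target_overlap must be in [0, 1], got {target_overlap!r}")
    rng = np.random.default_rng(seed)
    genes = np.array(truth.genes)
    cluster = designated_cluster or truth.clusters[0]
    rescue = sorted(truth.planted_rescue_down[cluster])

    rows: list[tuple[str, str, float]] = []
    membership: dict[str, frozenset[str]] = {}
    for t in range(n_tfs):
        tf = designated_tf if t == 0 else f"TF{t + 1:02d}"
        if t == 0:
            n_overlap = int(np.ceil(target_overlap * len(rescue))) if rescue else 0
            planted = list(rng.choice(rescue, size=n_overlap, replace=False)) if n_overlap else []
            n_extra = int(rng.integers(5, 20))
            pool = np.setdiff1d(genes, planted)
            extra = list(rng.choice(pool, size=n_extra, replace=False))
            targets = planted + extra
        else:
            n_targets = int(rng.integers(10, 50))
            targets = list(rng.choice(genes, size=n_targets, replace=False))
        imp = rng.lognormal(mean=1.0, sigma=1.0, size=len(targets))
        rows.extend((tf, g, float(w)) for g, w in zip(targets, imp))
        membership[tf] = frozenset(targets)

    truth.regulon_membership = membership
    table = pd.DataFrame(rows, columns=["TF", "target", "importance"])
    return table.sort_values(["TF", "target"], kind="mergesort").reset_index(drop=True)


def simulate_gene_sets(
    truth: GroundTruth,
    set_sizes: list[int] = (50, 50, 50, 50),
    seed: int = 0,
    enriched_share: float = 0.5,
):
    """Generate one planted-gene-enriched set plus uniform decoy sets.

    The first size becomes ``planted_disease_set``: an ``enriched_share``
    fraction of its members is drawn from the union of planted disease genes
    across clusters, the rest uniformly from the remaining genes. Each other
    size becomes a ``decoy_set_*`` drawn uniformly from the full universe.
    """
    from .enrichment import GeneSetCollection

    set_sizes = list(set_sizes)
    if not set_sizes:
        raise ConfigurationError("set_sizes must be non-empty")
    universe = np.array(truth.genes)
    if any(s > len(universe) or s < 1 for s in set_sizes):
        raise ConfigurationError("each set size must be in [1, n_genes]")
    rng = np.random.default_rng(seed)

    planted = sorted(
        set().union(*truth.planted_disease_up.values(), *truth.planted_disease_down.values())
    )
    sets: dict[str, frozenset[str]] = {}
    size0 = set_sizes[0]
    n_from_planted = min(len(planted), int(round(enriched_share * size0)))
    members = set(rng.choice(planted, size=n_from_planted, replace=False)) if n_from_planted else set()
    pool = np.setdiff1d(universe, sorted(members))
    members |= set(rng.choice(pool, size=size0 - len(members), replace=False))
    sets["planted_disease_set"] = frozenset(members)
    for i, s in enumerate(set_sizes[1:], start=1):
        sets[f"decoy_set_{i}"] = frozenset(rng.choice(universe, size=s, replace=False))
    return GeneSetCollection(sets=sets, universe=frozenset(universe))
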