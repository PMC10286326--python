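"""Generator contracts: determinism, planted-set invariants, mean structure."""

import numpy as np
import pytest
from scipy import stats

import screscue as sr
from screscue.errors import ConfigurationError


def _group_mask(adata, cluster, group):
    return ((adata.obs["cluster"] == cluster) & (adata.obs["group"] == group)).to_numpy()


class TestSimulateCounts:
    def test_same_seed_identical(self, small_cfg):
        a1, t1 = sr.simulate_counts(small_cfg, seed=3)
        a2, t2 = sr.simulate_counts(small_cfg, seed=3)
        assert (a1.X != a2.X).nnz == 0
        assert list(a1.obs_names) == list(a2.obs_names)
        assert t1.planted_rescue_down == t2.planted_rescue_down
        a3, _ = sr.simulate_counts(small_cfg, seed=4)
        assert (a1.X != a3.X).nnz > 0

    def test_zero_effect_empties_ground_truth(self):
        cfg = sr.SimConfig(n_clusters=2, cells_per_group_per_cluster=10, n_genes=100,
                           disease_effect_fraction=0.0)
        _, truth = sr.simulate_counts(cfg, seed=0)
        for sets in (truth.planted_disease_up, truth.planted_disease_down,
                     truth.planted_rescue_down, truth.planted_rescue_up):
            assert all(len(s) == 0 for s in sets.values())

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_ground_truth_subset_invariants(self, seed):
        cfg = sr.SimConfig(n_clusters=3, cells_per_group_per_cluster=5, n_genes=300)
        _, truth = sr.simulate_counts(cfg, seed=seed)
        for cl in truth.clusters:
            assert truth.planted_rescue_down[cl] <= truth.planted_disease_up[cl]
            assert truth.planted_rescue_up[cl] <= truth.planted_disease_down[cl]
            assert not truth.planted_disease_up[cl] & truth.planted_disease_down[cl]

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ConfigurationError):
            sr.simulate_counts(sr.SimConfig(n_genes=0), seed=0)
        with pytest.raises(ConfigurationError):
            sr.simulate_counts(sr.SimConfig(nb_dispersion=0.0), seed=0)
        with pytest.raises(ConfigurationError):
            sr.simulate_counts(sr.SimConfig(disease_effect_fraction=1.5), seed=0)

    def test_mito_flagging(self, small_data):
        adata, _ = small_data
        is_mito = adata.var["is_mito"].to_numpy()
        assert is_mito.sum() == round(0.05 * adata.n_vars)
        assert all(g.startswith("mt-") == m for g, m in zip(adata.var_names, is_mito))

    def test_baseline_mean_converges(self):
        """Flat baseline (sigma=0, no size-factor spread): per-gene mean -> exp(mu)."""
        cfg = sr.SimConfig(n_clusters=1, cells_per_group_per_cluster=3400, n_genes=60,
                           baseline_log_mean_sigma=0.0, libsize_sigma=0.0,
                           disease_effect_fraction=0.0)
        adata, _ = sr.simulate_counts(cfg, seed=5)
        X = adata.X.toarray()
        assert X.shape[0] >= 10_000
        mean = X.mean(axis=0)
        se = X.std(axis=0, ddof=1) / np.sqrt(X.shape[0])
        z = np.abs(mean - 1.0) / se  # exp(mu)=1
        assert (z < 3).mean() >= 0.95
        assert (z < 4.5).all()

    def test_rescued_and_nonrescued_group_means(self):
        cfg = sr.SimConfig(n_clusters=1, cells_per_group_per_cluster=2000, n_genes=300)
        adata, truth = sr.simulate_counts(cfg, seed=7)
        cl = truth.clusters[0]
        X = adata.X.toarray()
        naive = X[_group_mask(adata, cl, "naive")]
        disease = X[_group_mask(adata, cl, "disease")]
        treated = X[_group_mask(adata, cl, "treated")]
        gene_pos = {g: i for i, g in enumerate(adata.var_names)}

        def z_diff(A, B, genes):
            idx = [gene_pos[g] for g in genes]
            d = A[:, idx].mean(0) - B[:, idx].mean(0)
            se = np.sqrt(A[:, idx].var(0, ddof=1) / A.shape[0] + B[:, idx].var(0, ddof=1) / B.shape[0])
            return np.abs(d) / se

        rescued = sorted(truth.planted_rescue_down[cl] | truth.planted_rescue_up[cl])
        non_rescued = sorted(
            (truth.planted_disease_up[cl] | truth.planted_disease_down[cl]) - set(rescued)
        )
        z_r = z_diff(treated, naive, rescued)
        z_n = z_diff(treated, disease, non_rescued)
        assert (z_r < 3).mean() >= 0.9 and (z_r < 5).all()
        assert (z_n < 3).mean() >= 0.9 and (z_n < 5).all()
        # and the planted disease effect is really there
        z_effect = z_diff(disease, naive, sorted(truth.planted_disease_up[cl]))
        assert (z_effect > 3).all()


class TestSimulateRegulons:
    def test_full_overlap_contract(self, small_truth):
        reg = sr.simulate_regulons(small_truth, n_tfs=5, target_overlap=1.0, seed=1)
        targets = set(reg.loc[reg["TF"] == "TF01", "target"])
        assert small_truth.planted_rescue_down[small_truth.clusters[0]] <= targets
        assert small_truth.regulon_membership["TF01"] == frozenset(targets)

    def test_importances_positive_and_every_tf_nonempty(self, small_truth):
        reg = sr.simulate_regulons(small_truth, n_tfs=8, target_overlap=0.5, seed=2)
        assert (reg["importance"] > 0).all()
        assert reg.groupby("TF").size().min() >= 1
        assert reg["TF"].nunique() == 8

    def test_determinism_and_bad_config(self, small_truth):
        r1 = sr.simulate_regulons(small_truth, n_tfs=4, seed=9)
        r2 = sr.simulate_regulons(small_truth, n_tfs=4, seed=9)
        assert r1.equals(r2)
        with pytest.raises(ConfigurationError):
            sr.simulate_regulons(small_truth, n_tfs=0, seed=0)


class TestSimulateGeneSets:
    def test_enriched_set_beats_uniform_expectation(self, small_cfg):
        """Overlap of the enriched set with planted genes exceeds the uniform-draw
        expectation K*n/N in (almost) every of 20 seeds."""
        _, truth = sr.simulate_counts(small_cfg, seed=11)
        planted = set().union(*truth.planted_disease_up.values(),
                              *truth.planted_disease_down.values())
        N, n = len(truth.genes), len(planted)
        wins = 0
        for seed in range(20):
            coll = sr.simulate_gene_sets(truth, [40, 40], seed=seed)
            k = len(coll.sets["planted_disease_set"] & planted)
            wins += k > 40 * n / N
        assert wins >= 19

    def test_decoy_overlap_matches_hypergeometric_expectation(self, small_cfg):
        _, truth = sr.simulate_counts(small_cfg, seed=11)
        planted = set().union(*truth.planted_disease_up.values(),
                              *truth.planted_disease_down.values())
        N, n = len(truth.genes), len(planted)
        K = 40
        ks = [len(sr.simulate_gene_sets(truth, [40, K], seed=s).sets["decoy_set_1"] & planted)
              for s in range(20)]
        expect = K * n / N
        sd = np.sqrt(stats.hypergeom(N, n, K).var() / len(ks))
        assert abs(np.mean(ks) - expect) < 4 * sd

    def test_determinism_and_empty_sizes(self, small_truth):
        c1 = sr.simulate_gene_sets(small_truth, [20, 20], seed=3)
        c2 = sr.simulate_gene_sets(small_truth, [20, 20], seed=3)
        assert c1.sets == c2.sets
        with pytest.raises(ConfigurationError):
            sr.simulate_gene_sets(small_truth, [], seed=0)
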