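"""Wilcoxon rank-sum (exact + approximate), fold change, marker tables, DEG sets."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import screscue as sr
from screscue.errors import InputError


def brute_force_ranksum_p(x, y):
    """Independent oracle: two-sided p over every assignment of pooled ranks."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, N = len(x), len(x) + len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    mu = n * (N + 1) / 2
    obs = abs(ranks[:n].sum() - mu)
    hits = sum(
        1 for idx in combinations(range(N), n) if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-9
    )
    return hits / comb(N, n)


class TestWilcoxonRankSum:
    def test_fixed_case(self):
        w, p = sr.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
        assert w == 6.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_degenerate_all_tied(self):
        for mode in ("exact", "approx"):
            assert sr.wilcoxon_rank_sum([7, 7, 7, 7], [7, 7, 7, 7], mode)[1] == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            sr.wilcoxon_rank_sum([], [1, 2])

    @given(
        st.lists(st.integers(0, 5), min_size=3, max_size=6),
        st.lists(st.integers(0, 5), min_size=3, max_size=6),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_symmetry_and_bounds(self, x, y):
        _, pxy = sr.wilcoxon_rank_sum(x, y)
        _, pyx = sr.wilcoxon_rank_sum(y, x)
        assert pxy == pytest.approx(pyx, abs=1e-12)
        assert 0 < pxy <= 1

    def test_exact_equals_brute_force_with_ties(self, rng):
        for _ in range(60):
            n, m = rng.integers(3, 8, size=2)
            x = rng.integers(0, 6, n)
            y = rng.integers(0, 6, m)
            _, p = sr.wilcoxon_rank_sum(x, y, mode="exact")
            assert p == pytest.approx(brute_force_ranksum_p(x, y), abs=1e-12)

    def test_approx_calibrated_against_exact(self, rng):
        """The normal approximation tracks the exact p on average and never
        flips a clear significance call; pointwise agreement is limited by
        the lumpiness of the tied exact null at these sample sizes."""
        diffs = []
        for _ in range(100):
            n, m = rng.integers(5, 8, size=2)
            x = rng.integers(0, 8, n)
            y = rng.integers(0, 8, m)
            _, pe = sr.wilcoxon_rank_sum(x, y, mode="exact")
            _, pa = sr.wilcoxon_rank_sum(x, y, mode="approx")
            diffs.append(pa - pe)
            if pe > 0.3:
                assert pa > 0.05  # a clearly null exact p never looks significant
        assert np.mean(np.abs(diffs)) < 0.05
        assert abs(np.mean(diffs)) < 0.05  # no systematic bias

    def test_approx_matches_scipy_mannwhitney(self, rng):
        """Independent route: scipy's tie-corrected continuity-corrected normal p."""
        for _ in range(30):
            x = rng.integers(0, 10, 25)
            y = rng.integers(0, 10, 30)
            if np.ptp(np.concatenate([x, y])) == 0:
                continue
            _, p = sr.wilcoxon_rank_sum(x, y, mode="approx")
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            assert p == pytest.approx(ref, abs=1e-10)


class TestLog2FoldChange:
    def test_identity_and_antisymmetry(self, rng):
        a = rng.random(20)
        b = rng.random(15)
        assert sr.log2_fold_change(a, a) == 0.0
        assert sr.log2_fold_change(a, b) == pytest.approx(-sr.log2_fold_change(b, a), abs=1e-12)

    def test_direct_evaluation(self):
        a = np.full(10, np.log(2))  # expm1 -> 1
        b = np.zeros(10)
        assert sr.log2_fold_change(a, b) == pytest.approx(1.0, abs=1e-12)


class TestFindMarkers:
    def test_group_below_three_cells_refused(self, small_norm):
        tiny = small_norm[:50]  # cluster0 naive only
        with pytest.raises(InputError, match="minimum-3-cells"):
            sr.find_markers(tiny, "cluster0", "disease", "naive")

    def test_zero_expression_gene_absent(self, small_norm):
        table = sr.find_markers(small_norm, "cluster0", "disease", "naive")
        X = small_norm.layers["lognorm"]
        mask = ((small_norm.obs["cluster"] == "cluster0")
                & small_norm.obs["group"].isin(["disease", "naive"])).to_numpy()
        pct = np.asarray((X[mask] > 0).mean(axis=0)).ravel()
        silent = set(np.asarray(small_norm.var_names)[pct == 0])
        assert not silent & set(table["gene"])
        assert (np.maximum(table["pct_a"], table["pct_b"]) >= 0.1).all()

    def test_planted_gene_detected(self, small_norm, small_truth):
        table = sr.find_markers(small_norm, "cluster0", "disease", "naive").set_index("gene")
        planted_up = sorted(small_truth.planted_disease_up["cluster0"])
        hits = table.loc[table.index.intersection(planted_up)]
        # most planted |log2FC|=1 genes are significant at this sample size
        frac = ((hits["p"] < 0.05) & (hits["log2fc"] > 0.25)).mean()
        assert frac > 0.7

    def test_invariant_to_cell_and_gene_order(self, small_norm, rng):
        t1 = sr.find_markers(small_norm, "cluster1", "treated", "disease")
        perm_cells = rng.permutation(small_norm.n_obs)
        perm_genes = rng.permutation(small_norm.n_vars)
        shuffled = small_norm[perm_cells][:, perm_genes].copy()
        t2 = sr.find_markers(shuffled, "cluster1", "treated", "disease")
        pd.testing.assert_frame_equal(t1.reset_index(drop=True), t2.reset_index(drop=True))


class TestThresholdDEGs:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2fc", "p"])

    def test_strict_inequalities(self):
        table = self._table([
            ("at_lfc", 0.25, 0.001),    # excluded: |log2fc| not > 0.25
            ("up_ok", 0.30, 0.04),      # up
            ("at_p", -0.30, 0.05),      # excluded: p not < 0.05
            ("p_above", -0.30, 0.06),   # excluded
            ("down_ok", -0.26, 0.049),  # down
        ])
        degs = sr.threshold_degs(table, contrast="EAU", cell_type="ct")
        assert degs.up == {"up_ok"}
        assert degs.down == {"down_ok"}

    def test_up_down_disjoint(self, small_norm):
        table = sr.find_markers(small_norm, "cluster0", "disease", "naive")
        degs = sr.threshold_degs(table)
        assert not degs.up & degs.down


class TestComparableCelltypes:
    def test_boundary_missing_and_small(self):
        ann = pd.DataFrame({
            "cluster": ["a"] * 6 + ["b"] * 3 + ["c"] * 102,
            "group": ["x"] * 3 + ["y"] * 3 + ["x"] * 3 + ["x"] * 100 + ["y"] * 2,
        })
        out = sr.comparable_celltypes(ann, "x", "y")
        assert out == ["a"]  # b missing from y; c has only 2 cells in y

    def test_empty_annotation_rejected(self):
        with pytest.raises(InputError):
            sr.comparable_celltypes(pd.DataFrame(columns=["cluster", "group"]), "x", "y")


def test_null_calibration_small():
    """Rank-test false-positive rate stays near nominal on null synthetic data."""
    cfg = sr.SimConfig(n_clusters=1, cells_per_group_per_cluster=100, n_genes=800,
                       disease_effect_fraction=0.0)
    adata, _ = sr.simulate_counts(cfg, seed=21)
    norm = sr.normalize_cp10k(sr.apply_qc(adata, min_genes=0))
    table = sr.find_markers(norm, "cluster0", "disease", "naive")
    assert (table["p"] < 0.05).mean() <= 0.07
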