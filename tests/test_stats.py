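import warnings
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from surfmorph.stats import (CohortTable, adjust_for_age, analyze_statistic,
                             fdr_cdf, group_analysis, hotelling_map,
                             mapwise_permutation, t_stat_map,
                             vertex_permutation)


@pytest.fixture
def cohort36():
    rng = np.random.default_rng(0)
    groups = np.array([0] * 19 + [1] * 17)
    ages = np.where(groups == 0, rng.normal(45.1, 5.1, 36),
                    rng.normal(41.1, 5.0, 36))
    return CohortTable([f"s{i}" for i in range(36)], groups, ages)


class TestTStat:
    def test_identical_groups_give_zero(self):
        X = np.tile(np.arange(6.0)[:, None], (1, 4))
        g = np.array([0, 1, 0, 1, 0, 1])
        X[g == 1] = X[g == 0]
        assert np.abs(t_stat_map(X, g)).max() == 0.0

    def test_matches_scipy_formula(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((12, 40))
        g = np.array([0] * 6 + [1] * 6)
        ours = t_stat_map(X, g)
        ref = np.array([sps.ttest_ind(X[g == 1, v], X[g == 0, v],
                                      equal_var=True).statistic ** 2
                        for v in range(40)])
        assert np.abs(ours - ref).max() < 1e-12

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 20))
        g = np.array([0] * 5 + [1] * 5)
        assert np.allclose(t_stat_map(X, g), t_stat_map(X, 1 - g))

    def test_zero_variance_statistic_is_zero(self):
        X = np.ones((8, 3))
        g = np.array([0] * 4 + [1] * 4)
        assert (t_stat_map(X, g) == 0).all()


class TestHotelling:
    def test_equals_t2_in_dimension_one(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((14, 60))
        g = np.array([0] * 7 + [1] * 7)
        assert np.abs(hotelling_map(X[..., None], g) - t_stat_map(X, g)).max() < 1e-10

    def test_zero_for_identical_group_means(self):
        rng = np.random.default_rng(4)
        half = rng.standard_normal((5, 10, 3))
        X = np.concatenate([half, half])
        g = np.array([0] * 5 + [1] * 5)
        assert np.abs(hotelling_map(X, g)).max() < 1e-18

    def test_invariant_under_invertible_linear_channel_map(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((16, 25, 4))
        g = np.array([0] * 8 + [1] * 8)
        A = rng.standard_normal((4, 4)) + 3 * np.eye(4)
        assert np.abs(hotelling_map(X, g)
                      - hotelling_map(X @ A.T, g)).max() < 1e-6

    def test_insufficient_df_rejected(self):
        X = np.zeros((5, 4, 4))
        g = np.array([0, 0, 1, 1, 1])
        with pytest.raises(ValueError):
            hotelling_map(X, g)


class TestAgeAdjustment:
    def test_no_age_effect_leaves_values_nearly_unchanged(self, cohort36):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((36, 20))
        adj = adjust_for_age(X, cohort36)
        # only the (noisy) estimated age slope moves the values
        assert np.sqrt(np.mean((adj - X) ** 2)) < 0.25 * X.std()

    def test_pure_age_signal_removed_exactly(self, cohort36):
        X = np.tile(2.0 * cohort36.ages[:, None], (1, 7))
        adj = adjust_for_age(X, cohort36)
        assert adj.std(axis=0).max() < 1e-10

    def test_group_shift_preserved_and_slope_recovered(self, cohort36):
        rng = np.random.default_rng(7)
        X = (0.5 * cohort36.ages[:, None] + 1.0 * cohort36.groups[:, None]
             + rng.normal(0, 0.05, (36, 50)))
        adj = adjust_for_age(X, cohort36)
        shift = adj[cohort36.groups == 1].mean(0) - adj[cohort36.groups == 0].mean(0)
        assert np.abs(shift - 1.0).max() < 0.15
        # implied slope estimate: (X - adj) / (age - mean age)
        centered = cohort36.ages - cohort36.ages.mean()
        slopes = (X - adj)[np.argmax(np.abs(centered))] / centered[np.argmax(np.abs(centered))]
        assert np.abs(slopes - 0.5).max() < 0.1

    def test_constant_ages_warn_and_skip(self):
        coh = CohortTable(list("abcdef"), [0, 0, 0, 1, 1, 1], np.full(6, 42.0))
        X = np.random.default_rng(0).standard_normal((6, 4))
        with pytest.warns(UserWarning, match="constant ages"):
            adj = adjust_for_age(X, coh)
        assert np.array_equal(adj, X)


class TestVertexPermutation:
    def test_matches_exhaustive_enumeration_on_tiny_cohort(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((6, 9))
        g = np.array([0, 0, 0, 1, 1, 1])
        coh = CohortTable(list("abcdef"), g, 40 + rng.normal(0, 1, 6))
        with pytest.warns(UserWarning, match="exhaustively"):
            p = vertex_permutation(X, coh, n_perm=1000, seed=0)
        null = np.array([t_stat_map(X, np.isin(np.arange(6), idx).astype(int))
                         for idx in combinations(range(6), 3)])
        obs = t_stat_map(X, g)
        # same tolerant ">=" as the implementation so floating-point ties
        # between complementary splits do not flip a count
        p_ref = (1 + (null >= obs - 1e-9 * np.abs(obs)).sum(0)) / (1 + len(null))
        assert np.abs(p - p_ref).max() < 1e-12

    def test_constant_data_gives_p_one(self, cohort36):
        X = np.ones((36, 5))
        p = vertex_permutation(X, cohort36, n_perm=200, seed=0)
        assert (p == 1.0).all()

    def test_null_p_values_approximately_uniform(self, cohort36):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((36, 2000))
        p = vertex_permutation(X, cohort36, n_perm=1000, seed=1)
        assert sps.kstest(p, "uniform").statistic < 0.05

    def test_deterministic_given_seed(self, cohort36):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((36, 30))
        a = vertex_permutation(X, cohort36, n_perm=300, seed=5)
        b = vertex_permutation(X, cohort36, n_perm=300, seed=5)
        assert np.array_equal(a, b)


class TestMapwisePermutation:
    def test_threshold_one_gives_corrected_p_one(self, cohort36):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((36, 40))
        corrected, count, _ = mapwise_permutation(X, cohort36, threshold=1.0,
                                                  n_perm=200, seed=0)
        assert count == 40
        assert corrected == 1.0

    def test_strong_effect_detected(self, cohort36):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((36, 200))
        X[cohort36.groups == 1, :60] += 2.0
        corrected, count, _ = mapwise_permutation(X, cohort36, n_perm=1000, seed=0)
        assert corrected <= 0.01
        assert count >= 50

    def test_null_calibration_small(self, cohort36):
        # modest repeat count; the full 200-repeat calibration runs in the
        # acceptance suite
        rng = np.random.default_rng(13)
        rejections = 0
        reps = 40
        for r in range(reps):
            X = rng.standard_normal((36, 100))
            corrected, _, _ = mapwise_permutation(X, cohort36, n_perm=200,
                                                  seed=100 + r)
            rejections += corrected < 0.05
        assert rejections / reps < 0.15


class TestFdrCdf:
    def test_all_tiny_p_critical_is_max(self):
        crit, cdf = fdr_cdf(np.full(100, 1e-6), q=0.05)
        assert crit == pytest.approx(1e-6)
        assert cdf.shape == (100, 2)

    def test_uniform_p_usually_has_no_crossing(self):
        absent = 0
        for seed in range(20):
            p = np.random.default_rng(seed).uniform(0, 1, 1000)
            crit, _ = fdr_cdf(p, q=0.05)
            absent += crit is None
        assert absent >= 18

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.01, 0.2))
    def test_matches_benjamini_hochberg_step_up(self, seed, q):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 300) ** rng.integers(1, 4)
        crit, _ = fdr_cdf(p, q=q)
        reject = multipletests(p, q, method="fdr_bh")[0]
        if reject.any():
            assert crit == pytest.approx(p[reject].max())
        else:
            assert crit is None

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fdr_cdf(np.array([]), 0.05)


class TestGroupAnalysis:
    def test_statistics_subset_respected(self, cohort36):
        rng = np.random.default_rng(14)
        detJ = rng.standard_normal((36, 30)) + 1
        logS = rng.standard_normal((36, 30, 3))
        R = rng.standard_normal((36, 30)) + 4
        out = group_analysis(detJ, logS, R, cohort36, statistics=("detJ",),
                             n_perm=200, seed=0)
        assert set(out) == {"detJ"}

    def test_deterministic_p_maps(self, cohort36):
        rng = np.random.default_rng(15)
        logS = rng.standard_normal((36, 25, 3))
        a = analyze_statistic("logS", logS, cohort36, n_perm=300, seed=9)
        b = analyze_statistic("logS", logS, cohort36, n_perm=300, seed=9)
        assert np.array_equal(a.p_values, b.p_values)
        assert a.corrected_p == b.corrected_p

    def test_combined_concatenates_logS_and_R(self, cohort36):
        rng = np.random.default_rng(16)
        logS = rng.standard_normal((36, 20, 3))
        R = rng.standard_normal((36, 20)) + 4
        R[cohort36.groups == 1] += 1.5   # strong radial-only effect
        out = group_analysis(np.ones((36, 20)), logS, R, cohort36,
                             statistics=("logS", "combined"), n_perm=300, seed=2)
        # the combined statistic must see the radial effect that logS misses
        assert out["combined"].corrected_p < out["logS"].corrected_p
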