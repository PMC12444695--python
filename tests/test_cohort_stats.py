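"""Median split, group tests, correlation inference, clustering, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from bedmotion.cohort_stats import (
    bootstrap_ci,
    cluster_pipeline,
    compare_groups,
    fisher_exact_2xk,
    kmeans_cluster,
    median_split,
    pca_project,
    select_k_silhouette,
    spearman_perm,
    standardize,
)
from bedmotion.cohort_stats import test_normality as normality_test


def gaussian_copula_pair(rng, rho_s, n):
    """Bivariate sample with planted Spearman correlation rho_s."""
    r = 2 * np.sin(np.pi * rho_s / 6)
    z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=n)
    return z[:, 0], z[:, 1]


class TestMedianSplit:
    def test_even_cohort_splits_in_half(self):
        split = median_split(np.arange(1, 45, dtype=float))
        assert split.high.size == split.low.size == 22
        assert split.threshold == 22.5

    def test_odd_cohort_median_goes_low(self):
        split = median_split([1.0, 2.0, 3.0])
        assert split.threshold == 2.0
        assert split.high.tolist() == [2]
        assert split.low.tolist() == [0, 1]

    def test_identical_rates_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            median_split([5.0, 5.0, 5.0])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 8), min_size=2, max_size=60))
    def test_group_sizes_differ_by_at_most_one(self, rates):
        if len(set(rates)) < 2:
            return
        split = median_split([float(r) for r in rates])
        assert abs(split.high.size - split.low.size) <= 1
        assert split.high.size + split.low.size == len(rates)
        assert not set(split.high) & set(split.low)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table", [[[8, 2], [1, 5]], [[10, 10], [10, 10]], [[0, 5], [7, 0]], [[3, 0], [0, 0]]]
    )
    def test_2x2_matches_scipy(self, table):
        ours = fisher_exact_2xk(np.array(table))
        ref = stats.fisher_exact(np.array(table)).pvalue
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_2x3_detects_association(self):
        assert fisher_exact_2xk(np.array([[12, 1, 1], [1, 12, 1]])) < 0.001
        assert fisher_exact_2xk(np.array([[5, 5, 5], [5, 5, 5]])) == pytest.approx(1.0)


class TestCompareGroups:
    def _table(self, rng, shift=0.0, n=22):
        return pd.DataFrame(
            {
                "x": np.concatenate([rng.normal(0, 1, n), rng.normal(shift, 1, n)]),
                "svc": ["medicine"] * n + ["medicine"] * (n // 2) + ["cardiology"] * (n - n // 2),
            }
        ), np.array(["a"] * n + ["b"] * n)

    def test_identical_groups_fisher_p_is_one(self):
        table = pd.DataFrame({"svc": ["m", "c"] * 10})
        groups = np.array((["a"] * 10) + (["b"] * 10))
        table["svc"] = ["m"] * 5 + ["c"] * 5 + ["m"] * 5 + ["c"] * 5
        res = compare_groups(table, groups)
        assert res.loc[res.variable == "svc", "p"].item() == pytest.approx(1.0)

    def test_separated_gaussians_give_tiny_p(self, rng):
        table, groups = self._table(rng, shift=5.0)
        res = compare_groups(table, groups)
        assert res.loc[res.variable == "x", "p"].item() < 0.001

    def test_constant_variable_skipped_with_note(self):
        table = pd.DataFrame({"x": np.ones(10)})
        groups = np.array(["a"] * 5 + ["b"] * 5)
        res = compare_groups(table, groups)
        assert "constant" in res.loc[res.variable == "x", "note"].item()

    def test_single_level_category_skipped(self):
        table = pd.DataFrame({"svc": ["medicine"] * 10})
        groups = np.array(["a"] * 5 + ["b"] * 5)
        res = compare_groups(table, groups)
        assert "single level" in res.loc[res.variable == "svc", "note"].item()

    def test_welch_matches_scipy(self, rng):
        table, groups = self._table(rng, shift=1.0)
        res = compare_groups(table, groups)
        a = table.loc[groups == "a", "x"]
        b = table.loc[groups == "b", "x"]
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.loc[res.variable == "x", "p"].item() == pytest.approx(ref.pvalue)


class TestNormalityGate:
    def test_gaussian_sample_rarely_rejected(self, rng):
        w, p = normality_test(rng.normal(size=200))
        assert p > 0.01

    def test_lognormal_sample_rejected(self, rng):
        w, p = normality_test(np.exp(rng.normal(0, 1.5, size=200)))
        assert p < 0.01

    def test_constant_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            normality_test([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0])


class TestSpearmanPerm:
    def test_monotone_relation_gives_rho_one(self):
        x = np.arange(10.0)
        res = spearman_perm(x, np.exp(x), n_perm=200, seed=0)
        assert res.rho == pytest.approx(1.0)
        assert res.p_perm == 0.0

    def test_rho_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 5, 40).astype(float)  # heavy ties
        y = rng.integers(0, 5, 40).astype(float)
        res = spearman_perm(x, y, n_perm=10, seed=0)
        assert res.rho == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_p_close_to_reference_implementation(self, rng):
        x, y = gaussian_copula_pair(rng, 0.4, 44)
        res = spearman_perm(x, y, n_perm=10000, seed=1)
        ref_p = stats.spearmanr(x, y).pvalue
        assert abs(res.p_perm - ref_p) < 0.02

    def test_seed_reproducible(self, rng):
        x, y = gaussian_copula_pair(rng, 0.2, 30)
        a = spearman_perm(x, y, n_perm=500, seed=7)
        b = spearman_perm(x, y, n_perm=500, seed=7)
        assert a.p_perm == b.p_perm

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_perm(np.ones(10), np.arange(10.0))


class TestBootstrapCI:
    def test_fixed_seed_identical(self, rng):
        x, y = gaussian_copula_pair(rng, 0.5, 50)
        assert bootstrap_ci(x, y, 300, seed=3) == bootstrap_ci(x, y, 300, seed=3)

    def test_interval_narrows_with_n(self, rng):
        x, y = gaussian_copula_pair(rng, 0.5, 50)
        lo1, hi1 = bootstrap_ci(x, y, 500, seed=4)
        x4, y4 = np.tile(x, 4), np.tile(y, 4)
        lo4, hi4 = bootstrap_ci(x4, y4, 500, seed=4)
        assert hi4 - lo4 < hi1 - lo1

    def test_interval_contains_point_estimate(self, rng):
        x, y = gaussian_copula_pair(rng, 0.5, 100)
        rho = stats.spearmanr(x, y).statistic
        lo, hi = bootstrap_ci(x, y, 1000, seed=5)
        assert lo <= rho <= hi


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        df = pd.DataFrame({"a": rng.normal(5, 3, 50), "b": rng.uniform(0, 1000, 50)})
        z = standardize(df)
        assert np.allclose(z.mean(), 0, atol=1e-12)
        assert np.allclose(z.std(ddof=0), 1, atol=1e-12)

    def test_constant_column_dropped(self, rng, caplog):
        df = pd.DataFrame({"a": rng.normal(size=20), "c": np.full(20, 3.0)})
        with caplog.at_level("WARNING"):
            z = standardize(df)
        assert list(z.columns) == ["a"]


class TestClustering:
    def _blobs(self, rng, k, n_per=20, sep=10.0, d=4):
        centers = rng.normal(0, 1, (k, d))
        centers = centers / np.linalg.norm(centers, axis=1, keepdims=True) * sep
        centers *= np.arange(1, k + 1)[:, None]  # distinct radii: never overlapping
        X = np.vstack([c + rng.normal(0, 0.3, (n_per, d)) for c in centers])
        labels = np.repeat(np.arange(k), n_per)
        return X, labels

    def test_two_blobs_select_k2(self, rng):
        X, _ = self._blobs(rng, 2)
        k, scores = select_k_silhouette(X, range(2, 7), seed=0)
        assert k == 2

    def test_four_blobs_recovered_with_ari_one(self, rng):
        X, truth = self._blobs(rng, 4)
        k, _ = select_k_silhouette(X, range(2, 9), seed=0)
        assert k == 4
        labels = kmeans_cluster(X, 4, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert set(labels) == {1, 2, 3, 4}

    def test_deterministic_under_seed(self, rng):
        X = rng.uniform(0, 1, (30, 3))
        assert np.array_equal(kmeans_cluster(X, 3, seed=1), kmeans_cluster(X, 3, seed=1))

    def test_k_equals_n_each_point_own_cluster(self, rng):
        X = rng.normal(0, 1, (6, 2)) * 10
        labels = kmeans_cluster(X, 6, seed=0)
        assert len(set(labels)) == 6

    def test_k_above_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_cluster(rng.normal(size=(4, 2)), 5, seed=0)


class TestPCA:
    def test_collinear_data_first_component_explains_all(self, rng):
        x = rng.normal(size=100)
        X = np.column_stack([x, 3 * x])
        coords, evr = pca_project(X)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)
        assert evr[1] == pytest.approx(0.0, abs=1e-9)

    def test_isotropic_data_near_equal_shares(self, rng):
        X = rng.normal(size=(4000, 2))
        _, evr = pca_project(X)
        assert abs(evr[0] - evr[1]) < 0.06

    def test_projection_idempotent_in_component_subspace(self, rng):
        X = rng.normal(size=(50, 5))
        coords, _ = pca_project(X, n_components=2)
        coords2, _ = pca_project(coords, n_components=2)
        # re-projection only rotates/reflects within the subspace
        assert np.allclose(np.abs(coords2), np.abs(coords - coords.mean(axis=0)), atol=1e-8)

    def test_explained_fractions_sum_below_one(self, rng):
        _, evr = pca_project(rng.normal(size=(40, 6)))
        assert np.all((0 <= evr) & (evr <= 1)) and evr.sum() <= 1 + 1e-12


class TestClusterPipeline:
    def test_recovers_planted_structure_from_dataframe(self, rng):
        X, truth = TestClustering()._blobs(rng, 3, n_per=15)
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        res = cluster_pipeline(df, range(2, 7), seed=0)
        assert res.k == 3
        assert adjusted_rand_score(truth, res.labels) == 1.0
        assert res.pca_coords.shape == (45, 2)
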