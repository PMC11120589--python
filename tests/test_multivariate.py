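"""Correlation, clustering and PCA against brute-force oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from osmodry.multivariate import cluster_runs, pca_correlation, pearson_matrix


def brute_force_pearson(X: np.ndarray) -> np.ndarray:
    """Double-loop product-moment correlation, the textbook formula."""
    n, p = X.shape
    out = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            xi, xj = X[:, i] - X[:, i].mean(), X[:, j] - X[:, j].mean()
            out[i, j] = (xi * xj).sum() / np.sqrt((xi * xi).sum() * (xj * xj).sum())
    return out


def brute_force_complete_linkage(X: np.ndarray, metric="cityblock"):
    """Naive O(n^3) agglomeration; returns sorted merge heights."""
    from scipy.spatial.distance import cdist

    dist = cdist(X, X, metric=metric)
    clusters = [{i} for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
                if d < best[0]:
                    best = (d, (a, b))
        d, (a, b) = best
        heights.append(d)
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return np.array(heights)


class TestPearsonMatrix:
    def test_matches_brute_force_on_random_tables(self, toy_table_factory):
        rng = np.random.default_rng(11)
        X = rng.uniform(1.0, 9.0, size=(5, 4))
        table = toy_table_factory({f"c{i}": X[:, i] for i in range(4)})
        result = pearson_matrix(table)
        np.testing.assert_allclose(result.r.to_numpy(), brute_force_pearson(X), atol=1e-12)

    def test_pvalues_match_exact_t_transform(self, toy_table_factory):
        rng = np.random.default_rng(5)
        X = rng.uniform(0.0, 1.0, size=(8, 3))
        table = toy_table_factory({f"c{i}": X[:, i] for i in range(3)})
        result = pearson_matrix(table)
        for i in range(3):
            for j in range(i + 1, 3):
                r_ref, p_ref = stats.pearsonr(X[:, i], X[:, j])
                assert result.r.iloc[i, j] == pytest.approx(r_ref, abs=1e-12)
                assert result.p.iloc[i, j] == pytest.approx(p_ref, abs=1e-12)

    def test_self_correlation_is_one(self, table1):
        result = pearson_matrix(table1)
        np.testing.assert_allclose(np.diag(result.r.to_numpy()), 1.0)
        assert result.n == 15

    def test_perfect_anticorrelation(self, toy_table_factory):
        table = toy_table_factory({"x": [1, 2, 3], "y": [6, 4, 2]})
        result = pearson_matrix(table)
        assert result.r.loc["x", "y"] == pytest.approx(-1.0)
        assert result.p.loc["x", "y"] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, table1):
        result = pearson_matrix(table1)
        np.testing.assert_allclose(result.r.to_numpy(), result.r.to_numpy().T)
        np.testing.assert_allclose(result.p.to_numpy(), result.p.to_numpy().T)

    def test_constant_column_reported_missing(self, toy_table_factory):
        table = toy_table_factory({"x": [1, 2, 3], "flat": [4.0, 4.0, 4.0]})
        with pytest.warns(UserWarning, match="constant"):
            result = pearson_matrix(table)
        assert np.isnan(result.r.loc["x", "flat"])

    def test_needs_three_runs(self, toy_table_factory):
        table = toy_table_factory({"x": [1, 2], "y": [2, 1]})
        with pytest.raises(ValueError, match="at least 3"):
            pearson_matrix(table)


class TestClusterRuns:
    def test_one_dimensional_hand_agglomeration(self, toy_table_factory):
        """Points 0, 1, 10 on a line: merge {0,1} at height 1, all at height 10."""
        table = toy_table_factory({"x": [0.0, 1.0, 10.0]})
        result = cluster_runs(table, k=2)
        assert result.heights == pytest.approx([1.0, 10.0])
        assert result.labels[1] == result.labels[2] != result.labels[3]

    def test_identical_runs_merge_at_zero(self, toy_table_factory):
        table = toy_table_factory({"x": [5.0, 5.0, 9.0], "y": [1.0, 1.0, 3.0]})
        result = cluster_runs(table, k=2)
        assert result.heights[0] == pytest.approx(0.0)

    def test_heights_match_brute_force_oracle(self, toy_table_factory):
        rng = np.random.default_rng(23)
        X = rng.uniform(0.0, 10.0, size=(8, 5))
        table = toy_table_factory({f"c{i}": X[:, i] for i in range(5)})
        result = cluster_runs(table, k=2)
        np.testing.assert_allclose(result.heights, brute_force_complete_linkage(X),
                                   atol=1e-10)

    def test_heights_monotone_nondecreasing(self, table1):
        result = cluster_runs(table1)
        assert np.all(np.diff(result.heights) >= -1e-12)

    def test_labels_partition_all_runs(self, table1):
        result = cluster_runs(table1, k=4)
        members = result.members()
        assert sorted(r for group in members.values() for r in group) == table1.run_ids
        assert len(members) == 4

    def test_k_larger_than_n_rejected(self, toy_table_factory):
        table = toy_table_factory({"x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="cannot cut"):
            cluster_runs(table, k=5)


class TestPCACorrelation:
    def test_two_perfectly_correlated_variables(self, toy_table_factory):
        table = toy_table_factory({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 6.0]})
        result = pca_correlation(table)
        assert result.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-12)
        assert result.percent_variance[0] == pytest.approx(100.0)

    def test_reconstructs_correlation_matrix(self, table1):
        result = pca_correlation(table1)
        L = result.loadings.to_numpy()
        reconstruction = L @ np.diag(result.eigenvalues) @ L.T
        corr = np.corrcoef(table1.responses().to_numpy(), rowvar=False)
        np.testing.assert_allclose(reconstruction, corr, atol=1e-8)

    def test_variance_decomposition_normalizations(self, table1):
        result = pca_correlation(table1)
        assert result.percent_variance.sum() == pytest.approx(100.0)
        assert result.eigenvalues.sum() == pytest.approx(13.0)
        np.testing.assert_allclose(result.contributions.sum(axis=0), 100.0)
        assert np.all(np.diff(result.eigenvalues) <= 1e-12)

    def test_component_sign_convention(self, table1):
        result = pca_correlation(table1)
        for column in result.loadings:
            loading = result.loadings[column]
            assert loading.iloc[np.argmax(np.abs(loading.to_numpy()))] > 0

    def test_constant_column_named_in_error(self, toy_table_factory):
        table = toy_table_factory({"x": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        with pytest.raises(ValueError, match="flat"):
            pca_correlation(table)

    def test_column_subset_selection(self, table1):
        result = pca_correlation(table1, columns=["DMC", "WL", "K"])
        assert list(result.loadings.index) == ["DMC", "WL", "K"]
        assert result.eigenvalues.sum() == pytest.approx(3.0)
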