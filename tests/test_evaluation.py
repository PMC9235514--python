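import numpy as np
import pytest

from densitree.evaluation import (
    ari_clustering_agreement,
    auc_over_k,
    distance_correlations,
    evaluate_embedding,
    knn_preservation,
    relative_scores,
    report_table,
    voronoi_agreement,
)


def rigid_transform(X, rng):
    angle = rng.uniform(0, 2 * np.pi)
    R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    return X @ R.T + rng.uniform(-5, 5, size=2)


class TestARI:
    def test_identity_embedding(self, three_branch_2d):
        X, _ = three_branch_2d
        assert ari_clustering_agreement(X.values, X.values.copy(), k=8, seed=0) == 1.0

    def test_unrelated_spaces_near_zero(self, rng):
        high = rng.standard_normal((2000, 5))
        low = rng.standard_normal((2000, 2))
        assert abs(ari_clustering_agreement(high, low, k=10, seed=0)) < 0.05

    def test_invalid_k(self, rng):
        with pytest.raises(ValueError):
            ari_clustering_agreement(rng.random((5, 2)), rng.random((5, 2)), k=1)


class TestKnnPreservation:
    def test_identity_is_one(self, two_clusters):
        X, _ = two_clusters
        assert knn_preservation(X.values, X.values.copy(), k=5) == 1.0

    def test_all_neighbours_trivial(self, rng):
        high = rng.standard_normal((30, 4))
        low = rng.standard_normal((30, 2))
        assert knn_preservation(high, low, k=29) == 1.0

    def test_matches_brute_force(self, rng):
        high = rng.standard_normal((5, 3))
        low = rng.standard_normal((5, 2))
        expected = []
        for i in range(5):
            dh = [(np.linalg.norm(high[i] - high[j]), j) for j in range(5) if j != i]
            dl = [(np.linalg.norm(low[i] - low[j]), j) for j in range(5) if j != i]
            top_h = {j for _, j in sorted(dh)[:2]}
            top_l = {j for _, j in sorted(dl)[:2]}
            expected.append(len(top_h & top_l) / 2)
        assert knn_preservation(high, low, k=2) == pytest.approx(np.mean(expected))

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError):
            knn_preservation(rng.random((5, 2)), rng.random((5, 2)), k=5)


class TestDistanceCorrelations:
    def test_rigid_isometry_perfect(self, rng):
        X = rng.standard_normal((60, 2))
        low = rigid_transform(X, rng)
        p, s = distance_correlations(X, low, "euclidean")
        assert p == pytest.approx(1.0, abs=1e-12)
        assert s == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_embedding_reports_zero(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.warns(UserWarning, match="degenerate"):
            assert distance_correlations(X, np.zeros((20, 2))) == (0.0, 0.0)

    def test_collinear_swap_spearman(self):
        # frozen from rank correlation of the 6 pairwise distances by hand
        high = np.array([[0.0], [1.0], [2.0], [3.0]])
        low = np.array([[0.0], [1.0], [3.0], [2.0]])
        _, s = distance_correlations(high, low, "euclidean")
        assert s == pytest.approx(0.43333333333333335)

    def test_geodesic_on_curved_data(self, three_branch_2d):
        X, _ = three_branch_2d
        p, s = distance_correlations(X.values, X.values.copy(), "geodesic", knn_k=10)
        assert p > 0.5 and s > 0.5  # identity embedding, positive association

    def test_subsampling_is_seeded(self, rng):
        high = rng.standard_normal((3500, 4))
        low = high[:, :2]
        a = distance_correlations(high, low, "euclidean", seed=11)
        b = distance_correlations(high, low, "euclidean", seed=11)
        assert a == b


class TestVoronoiAgreement:
    def test_identity_both_orders(self, three_branch_2d):
        X, _ = three_branch_2d
        for order in (1, 2):
            assert voronoi_agreement(X.values, X.values.copy(), k=8, order=order) == 1.0

    def test_collapsed_clusters_bounded(self, two_clusters):
        X, _ = two_clusters
        collapsed = np.zeros((X.n, 2))
        value = voronoi_agreement(X.values, collapsed, k=2, order=1, seed=0)
        assert value <= 0.5 + 1e-12  # at most the larger cluster's share

    def test_order_two_matches_brute_force(self, rng):
        high = rng.standard_normal((40, 3))
        low = rng.standard_normal((40, 2))
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=4, n_init=10, random_state=0).fit(high)
        seeds = np.stack([low[km.labels_ == c].mean(axis=0) for c in range(4)])
        expected = []
        for i in range(40):
            dh = np.linalg.norm(high[i] - km.cluster_centers_, axis=1)
            dl = np.linalg.norm(low[i] - seeds, axis=1)
            expected.append(
                set(np.argsort(dh, kind="stable")[:2]) == set(np.argsort(dl, kind="stable")[:2])
            )
        value = voronoi_agreement(high, low, k=4, order=2, seed=0)
        assert value == pytest.approx(np.mean(expected))

    def test_rigid_invariance(self, two_clusters, rng):
        X, _ = two_clusters
        low = X.values[:, :2]
        moved = rigid_transform(low, rng)
        for order in (1, 2):
            assert voronoi_agreement(X.values, low, 4, order, 0) == pytest.approx(
                voronoi_agreement(X.values, moved, 4, order, 0)
            )


class TestAggregation:
    def test_auc_of_constant(self):
        assert auc_over_k(lambda k: 0.7) == pytest.approx(0.7)

    def test_auc_of_linear_metric(self):
        # mean of 0.01 ... 0.10 over the default 10-point grid
        assert auc_over_k(lambda k: 0.1 * k / 100) == pytest.approx(0.055)

    def test_auc_empty_grid(self):
        with pytest.raises(ValueError):
            auc_over_k(lambda k: 1.0, [])

    def test_relative_scores(self):
        assert relative_scores({"A": 0.8, "B": 0.4}) == {"A": 100.0, "B": 50.0}
        assert relative_scores({"only": 0.3}) == {"only": 100.0}
        lower = relative_scores({"A": 2.0, "B": 4.0}, higher_is_better=False)
        assert lower == {"A": 100.0, "B": 50.0}
        with pytest.raises(ValueError):
            relative_scores({"A": 0.0, "B": 0.0})


class TestFullReport:
    def test_identity_embedding_maximal(self, three_branch_2d):
        X, _ = three_branch_2d
        report = evaluate_embedding(
            X.values, X.values.copy(), k_grid=(5, 10), seed=0, geodesic_knn=10
        )
        assert report.ari_auc == 1.0
        assert report.knn_auc == 1.0
        assert report.voronoi1_auc == 1.0
        assert report.voronoi2_auc == 1.0
        assert report.pearson_euclidean == pytest.approx(1.0, abs=1e-12)
        assert report.spearman_euclidean == pytest.approx(1.0, abs=1e-12)

    def test_report_table_shape(self, three_branch_2d):
        X, _ = three_branch_2d
        report = evaluate_embedding(X.values, X.values.copy(), k_grid=(5,), seed=0)
        table = report_table({"identity": report})
        assert table.shape == (1, 9)
        assert table.loc["identity", "mean"] == pytest.approx(report.mean())
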