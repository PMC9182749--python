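"""Feature scaling, k-means contracts, silhouette and sign labels."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score, silhouette_score

from hbregimes.clustering import (
    ClusterModel,
    assign_sign_labels,
    kmeans,
    scale_features,
    select_k,
    silhouette,
)


def four_blobs(rng, n_per=50, centers=((1.2, 1.2), (1.2, -1.2), (-1.2, 1.2), (-1.2, -1.2)),
               sigma=0.1):
    pts, labels = [], []
    for j, c in enumerate(centers):
        pts.append(np.asarray(c) + sigma * rng.standard_normal((n_per, 2)))
        labels += [j] * n_per
    return np.vstack(pts), np.array(labels)


def silhouette_brute(points, labels):
    """Literal double-loop transcription of the per-point definition."""
    n = len(points)
    s = np.zeros(n)
    clusters = sorted(set(labels))
    for i in range(n):
        mine = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not mine:
            continue
        a = np.mean([np.linalg.norm(points[i] - points[j]) for j in mine])
        b = min(
            np.mean([np.linalg.norm(points[i] - points[j])
                     for j in range(n) if labels[j] == c])
            for c in clusters if c != labels[i]
        )
        s[i] = (b - a) / max(a, b)
    return s


class TestScaling:
    def test_gaussian_alpha_unchanged(self):
        ok = 0
        for s in range(100):
            r = np.random.default_rng(s)
            pts, scaling = scale_features(r.standard_normal(800),
                                          r.standard_normal(800), alpha=3.0)
            ok += scaling.coverage >= 0.99 and scaling.alpha == 3.0
        assert ok >= 95

    def test_centered_output(self, rng):
        de, dh = 5 + rng.standard_normal(500), -2 + rng.standard_normal(500)
        pts, _ = scale_features(de, dh)
        assert abs(pts[:, 0].mean()) < 1e-12
        assert abs(pts[:, 1].mean()) < 1e-12

    def test_heavy_tails_adjust_alpha(self, rng):
        de = rng.standard_t(3, 3000)
        dh = rng.standard_t(3, 3000)
        pts, scaling = scale_features(de, dh, alpha=3.0)
        assert scaling.alpha > 3.0
        assert scaling.coverage >= 0.99
        # oracle: the recorded alpha covers the 99% quantile by construction
        zmax = np.maximum(np.abs(de - de.mean()) / de.std(),
                          np.abs(dh - dh.mean()) / dh.std())
        assert np.mean(zmax <= scaling.alpha) >= 0.99

    def test_zero_sd_errors(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            scale_features(np.ones(10), np.arange(10.0))


class TestKmeans:
    def test_k1_is_mean(self, rng):
        pts = rng.standard_normal((40, 2))
        model = kmeans(pts, 1, seed=0)
        np.testing.assert_allclose(model.centroids[0], pts.mean(axis=0), atol=1e-12)

    def test_planted_blobs_perfect_recovery(self, rng):
        pts, truth = four_blobs(rng)
        model = kmeans(pts, 4, seed=0)
        assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_matches_exhaustive_optimum(self, rng):
        pts = rng.standard_normal((8, 2))
        best = np.inf
        for assign in itertools.product([0, 1], repeat=8):
            assign = np.array(assign)
            if assign.min() == assign.max():
                continue
            obj = sum(
                np.sum((pts[assign == j] - pts[assign == j].mean(axis=0)) ** 2)
                for j in (0, 1)
            )
            best = min(best, obj)
        model = kmeans(pts, 2, n_init=50, seed=0)
        assert model.objective == pytest.approx(best, rel=1e-10)

    def test_objective_non_increasing(self, rng):
        pts = rng.standard_normal((300, 2))
        model = kmeans(pts, 5, seed=1)
        hist = np.array(model.objective_history)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_fixed_point(self, rng):
        pts = rng.standard_normal((200, 2))
        model = kmeans(pts, 4, seed=2)
        dist2 = cdist(pts, model.centroids, "sqeuclidean")
        np.testing.assert_array_equal(np.argmin(dist2, axis=1), model.labels)

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValueError):
            kmeans(rng.standard_normal((3, 2)), 4)


class TestSilhouette:
    def test_hand_example(self):
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([0, 0, 1, 1])
        rep = silhouette(pts, labels)
        assert rep.values[0] == pytest.approx((10.5 - 1.0) / 10.5)
        assert rep.values[0] == pytest.approx(0.9048, abs=1e-4)

    def test_singleton_cluster_zero(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        rep = silhouette(pts, np.array([0, 0, 1]))
        assert rep.values[2] == 0.0

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError):
            silhouette(np.random.randn(5, 2), np.zeros(5, dtype=int))

    def test_matches_brute_force(self):
        for s in range(20):
            r = np.random.default_rng(s)
            n = int(r.integers(10, 200))
            pts = r.standard_normal((n, 2))
            labels = r.integers(0, 4, n)
            if len(set(labels)) < 2:
                continue
            mine = silhouette(pts, labels).values
            np.testing.assert_allclose(mine, silhouette_brute(pts, labels),
                                       atol=1e-12)

    def test_matches_sklearn_on_clean_case(self, rng):
        # sklearn agrees whenever no singleton clusters are involved
        pts, truth = four_blobs(rng, n_per=30)
        rep = silhouette(pts, truth)
        assert rep.mean == pytest.approx(silhouette_score(pts, truth), abs=1e-12)

    def test_random_labels_near_zero(self, rng):
        pts = rng.standard_normal((300, 2))
        labels = rng.integers(0, 3, 300)
        assert abs(silhouette(pts, labels).mean) < 0.1


class TestSelectK:
    def test_four_blobs(self, rng):
        pts, _ = four_blobs(rng)
        k, scores = select_k(pts, range(2, 11), seed=0)
        assert k == 4

    def test_two_blobs(self, rng):
        pts, _ = four_blobs(rng, centers=((2.0, 0.0), (-2.0, 0.0)))
        k, _ = select_k(pts, range(2, 8), seed=0)
        assert k == 2

    def test_unstructured_warns_weak(self, rng):
        # a single Gaussian blob has no cluster structure; best mean
        # silhouette sits well below the 0.4 weak-structure threshold
        pts = rng.standard_normal((200, 2))
        with pytest.warns(UserWarning, match="weak cluster structure"):
            k, scores = select_k(pts, range(2, 7), seed=0)
        assert scores[k] < 0.4

    def test_uniform_square_low_score(self, rng):
        pts = rng.uniform(-1, 1, (200, 2))
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            k, scores = select_k(pts, range(2, 7), seed=0)
        assert scores[k] < 0.5  # no real structure in a uniform square

    def test_range_clipped(self, rng):
        pts = rng.standard_normal((6, 2))
        with pytest.warns(UserWarning, match="clipped"):
            select_k(pts, range(2, 30), seed=0)


class TestSignLabels:
    def _model(self, centroids_raw, scaling):
        scaled = scaling.transform(centroids_raw[:, 0], centroids_raw[:, 1])
        return ClusterModel(k=len(centroids_raw), centroids=scaled,
                            labels=np.arange(len(centroids_raw)), objective=0.0)

    def _identity_scaling(self):
        from hbregimes.clustering import FeatureScaling

        return FeatureScaling(0.0, 0.0, 1.0, 1.0, 1.0, 1.0)

    def test_published_centroid_labels(self):
        scaling = self._identity_scaling()
        cents = np.array([[-1.29, 1.13], [1.30, -1.06], [1.24, 1.16], [-1.25, -1.20]])
        model = self._model(cents, scaling)
        labels = assign_sign_labels(model, scaling)
        assert labels == {0: "-/+", 1: "+/-", 2: "+/+", 3: "-/-"}

    def test_duplicate_signs_error(self):
        scaling = self._identity_scaling()
        cents = np.array([[1.0, 1.0], [2.0, 2.0], [-1.0, 1.0], [-1.0, -1.0]])
        model = self._model(cents, scaling)
        with pytest.raises(ValueError, match="sign-separated"):
            assign_sign_labels(model, scaling)

    def test_axis_boundary_counts_positive(self):
        scaling = self._identity_scaling()
        cents = np.array([[0.0, 1.0], [1.0, -1.0], [-1.0, 1.0]])
        model = self._model(cents, scaling)
        with pytest.warns(UserWarning, match="boundary"):
            labels = assign_sign_labels(model, scaling)
        assert labels[0] == "+/+"
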