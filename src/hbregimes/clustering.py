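"""Regime clustering in the (Delta-E, Delta-HR) plane.

Features are rescaled per axis by ``(x - mean) / (alpha * sd)`` with a
tunable alpha (default 3) adjusted upward, by direct quantile search, until
at least 99% of the points fall in the unit square.  Clustering is Lloyd's
k-means with k-means++ seeding and the L2 objective

    E(C) = sum_j sum_{x in C_j} ||x - c_j||^2 ,

the total intracluster squared error; iterations stop when no point is
reassigned or no centroid moves more than the tolerance.  The number of
clusters is selected by the mean silhouette score, and with k = 4 each
centroid is named by the signs of its unscaled (Delta-E, Delta-HR)
coordinates — the four heartbeat-dynamics regimes +/+, +/-, -/+, -/-.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "SIGN_LABELS",
    "FeatureScaling",
    "ClusterModel",
    "SilhouetteReport",
    "scale_features",
    "kmeans",
    "silhouette",
    "select_k",
    "assign_sign_labels",
]

#: The four regimes, written sign(Delta-E)/sign(Delta-HR).
SIGN_LABELS = ("+/+", "+/-", "-/+", "-/-")


@dataclass
class FeatureScaling:
    """Per-axis affine rescaling of (Delta-E, Delta-HR)."""

    mean_e: float
    mean_hr: float
    s_e: float
    s_hr: float
    alpha: float
    coverage: float

    def transform(self, delta_e, delta_hr) -> np.ndarray:
        x = (np.asarray(delta_e) - self.mean_e) / (self.alpha * self.s_e)
        y = (np.asarray(delta_hr) - self.mean_hr) / (self.alpha * self.s_hr)
        return np.column_stack([x, y])

    def inverse(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        return np.column_stack(
            [
                points[:, 0] * self.alpha * self.s_e + self.mean_e,
                points[:, 1] * self.alpha * self.s_hr + self.mean_hr,
            ]
        )


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray  # scaled space, shape (k, 2)
    labels: np.ndarray  # cluster index per point
    objective: float
    objective_history: list = field(default_factory=list)
    n_iter: int = 0
    mean_silhouette: float | None = None
    sign_labels: dict | None = None  # cluster index -> "+/-" style name


@dataclass
class SilhouetteReport:
    values: np.ndarray
    mean: float
    per_k: dict | None = None
    chosen_k: int | None = None


def scale_features(delta_e, delta_hr, alpha: float = 3.0):
    """Center and rescale features so ~all points fit in [-1, 1]^2.

    For near-Gaussian features alpha = 3 already captures > 99% per axis.
    Otherwise alpha grows to the smallest value covering 99% of the points,
    found directly from the empirical quantile of the per-point max
    standardized coordinate.  Returns ``(points, FeatureScaling)``.
    """
    de = np.asarray(delta_e, dtype=float)
    dh = np.asarray(delta_hr, dtype=float)
    if de.size < 2:
        raise ValueError("need at least 2 windows to scale")
    if not (np.isfinite(de).all() and np.isfinite(dh).all()):
        raise ValueError("non-finite feature values")
    m_e, m_h = de.mean(), dh.mean()
    s_e, s_h = de.std(), dh.std()
    if s_e == 0 or s_h == 0:
        raise ValueError("zero standard deviation on a feature axis")
    zmax = np.maximum(np.abs(de - m_e) / s_e, np.abs(dh - m_h) / s_h)
    cover = float(np.mean(zmax <= alpha))
    if cover < 0.99:
        alpha = float(np.quantile(zmax, 0.99, method="higher"))
        cover = float(np.mean(zmax <= alpha))
    scaling = FeatureScaling(m_e, m_h, s_e, s_h, float(alpha), cover)
    return scaling.transform(de, dh), scaling


# ---------------------------------------------------------------------------
# k-means (Lloyd iterations, k-means++ seeding)


def _kmeanspp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = points.shape[0]
    centers = np.empty((k, points.shape[1]))
    centers[0] = points[rng.integers(n)]
    d2 = np.sum((points - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total == 0:  # all points coincide with chosen centers
            centers[j] = points[rng.integers(n)]
            continue
        centers[j] = points[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((points - centers[j]) ** 2, axis=1))
    return centers


def _lloyd(points: np.ndarray, centers: np.ndarray, tol: float, max_iter: int):
    labels = np.full(points.shape[0], -1)
    history = []
    for it in range(1, max_iter + 1):
        dist2 = cdist(points, centers, "sqeuclidean")
        new_labels = np.argmin(dist2, axis=1)
        obj = float(dist2[np.arange(points.shape[0]), new_labels].sum())
        history.append(obj)
        no_reassign = np.array_equal(new_labels, labels)
        labels = new_labels
        new_centers = centers.copy()
        for j in range(centers.shape[0]):
            members = points[labels == j]
            if members.shape[0] == 0:
                # empty cluster: relocate to the point farthest from the
                # former centroid (Lloyd leaves this case unspecified)
                far = np.argmax(np.sum((points - centers[j]) ** 2, axis=1))
                new_centers[j] = points[far]
            else:
                new_centers[j] = members.mean(axis=0)
        shift = np.sqrt(np.sum((new_centers - centers) ** 2, axis=1)).max()
        centers = new_centers
        if no_reassign or shift < tol:
            break
    # final sync of labels/objective with the converged centroids
    dist2 = cdist(points, centers, "sqeuclidean")
    labels = np.argmin(dist2, axis=1)
    obj = float(dist2[np.arange(points.shape[0]), labels].sum())
    history.append(obj)
    return centers, labels, obj, history, it


def kmeans(
    points: np.ndarray,
    k: int,
    tol: float = 1e-5,
    n_init: int = 10,
    seed=None,
    max_iter: int = 300,
) -> ClusterModel:
    """Best-of-``n_init`` Lloyd runs from k-means++ starts.

    The objective (total intracluster squared error) is recorded after each
    assignment step and is non-increasing within a run; the best run by
    final objective wins.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be 2-D (n_samples, n_features)")
    n = points.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for {n} points")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centers0 = _kmeanspp_init(points, k, rng)
        centers, labels, obj, history, n_iter = _lloyd(points, centers0, tol, max_iter)
        if best is None or obj < best.objective:
            best = ClusterModel(
                k=k,
                centroids=centers,
                labels=labels,
                objective=obj,
                objective_history=history,
                n_iter=n_iter,
            )
    return best


# ---------------------------------------------------------------------------
# Silhouette


def silhouette(points: np.ndarray, labels: np.ndarray) -> SilhouetteReport:
    """Per-point silhouette values s_i = (b_i - a_i) / max(a_i, b_i).

    a_i is the mean distance to the other members of the point's cluster
    (divisor n_A - 1); b_i the smallest mean distance to any other cluster.
    Points in singleton clusters get s_i = 0.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    dist = cdist(points, points)
    n = points.shape[0]
    s = np.zeros(n)
    sums = {c: dist[:, labels == c].sum(axis=1) for c in uniq}
    counts = {c: int((labels == c).sum()) for c in uniq}
    for i in range(n):
        c = labels[i]
        if counts[c] == 1:
            s[i] = 0.0
            continue
        a = sums[c][i] / (counts[c] - 1)
        b = min(sums[o][i] / counts[o] for o in uniq if o != c)
        s[i] = (b - a) / max(a, b)
    return SilhouetteReport(values=s, mean=float(s.mean()))


def select_k(
    points: np.ndarray,
    k_range=range(2, 11),
    tol: float = 1e-5,
    n_init: int = 10,
    seed=None,
    weak_threshold: float = 0.4,
):
    """Choose k by maximal mean silhouette (ties -> smallest k).

    Returns ``(chosen_k, per_k_scores)``.  The range is clipped to
    [2, n - 1] with a warning; a best score below ``weak_threshold`` raises
    a "weak cluster structure" warning.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("no admissible k in range")
    if len(ks) < len(list(k_range)):
        warnings.warn("k range clipped to [2, n-1]", stacklevel=2)
    rng = np.random.default_rng(seed)
    scores = {}
    for k in ks:
        model = kmeans(points, k, tol=tol, n_init=n_init,
                       seed=rng.integers(2**31 - 1))
        scores[k] = silhouette(points, model.labels).mean
    chosen = max(sorted(scores), key=lambda k: scores[k])
    if scores[chosen] < weak_threshold:
        warnings.warn(
            f"weak cluster structure: best mean silhouette {scores[chosen]:.3f}",
            stacklevel=2,
        )
    return chosen, scores


# ---------------------------------------------------------------------------
# Sign labels


def _sign_char(value: float) -> str:
    # boundary rule: exact zero counts as "+"
    return "+" if value >= 0 else "-"


def assign_sign_labels(model: ClusterModel, scaling: FeatureScaling) -> dict:
    """Name each cluster by the signs of its unscaled centroid.

    Labels read sign(Delta-E)/sign(Delta-HR).  With k = 4 the four labels
    must be distinct — overlapping sign pairs mean the clusters do not
    correspond to the four dynamic regimes.  A centroid exactly on an axis
    is labeled "+" on that axis (and flagged with a warning).
    """
    raw = scaling.inverse(model.centroids)
    labels = {}
    for j, (de, dh) in enumerate(raw):
        if de == 0 or dh == 0:
            warnings.warn(f"centroid {j} lies on a sign boundary", stacklevel=2)
        labels[j] = f"{_sign_char(de)}/{_sign_char(dh)}"
    if model.k == 4 and len(set(labels.values())) != 4:
        raise ValueError("clusters not sign-separated: duplicate sign pairs at k=4")
    model.sign_labels = labels
    return labels
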