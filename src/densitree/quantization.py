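"""Vector quantization of expression profiles and second-order Voronoi lookup.

The tree-extraction step summarises a cells-by-genes matrix with ``k``
k-means centroids.  Each data point is then characterised by its *ordered*
two nearest centroids, i.e. by the second-order Voronoi region it falls in;
those pairs drive both the Hebbian edge weights and the push-pull loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

__all__ = ["ExpressionMatrix", "Quantization", "NearestTwo", "fit_quantization", "nearest_two"]


@dataclass(frozen=True)
class ExpressionMatrix:
    """An ``n x d`` matrix of cells by features, preprocessed upstream.

    The method consumes continuous, already-normalised expression values;
    no internal preprocessing is applied.
    """

    values: np.ndarray
    row_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]
    col_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("expression matrix must be 2-D (cells x features)")
        n, d = values.shape
        if n < 2 or d < 1:
            raise ValueError(f"need at least 2 cells and 1 feature, got {n} x {d}")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")
        object.__setattr__(self, "values", values)
        row_ids = self.row_ids if self.row_ids is not None else [f"cell{i}" for i in range(n)]
        col_ids = self.col_ids if self.col_ids is not None else [f"feature{j}" for j in range(d)]
        row_ids, col_ids = list(map(str, row_ids)), list(map(str, col_ids))
        if len(row_ids) != n or len(col_ids) != d:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(row_ids)) != n:
            raise ValueError("row_ids must be unique")
        if len(set(col_ids)) != d:
            raise ValueError("col_ids must be unique")
        object.__setattr__(self, "row_ids", row_ids)
        object.__setattr__(self, "col_ids", col_ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Quantization:
    """k-means centroids plus the per-point hard assignment."""

    centroids: np.ndarray  # k x d
    assignment: np.ndarray  # n ints in [0, k)
    k: int

    def __post_init__(self):
        object.__setattr__(self, "centroids", np.asarray(self.centroids, dtype=np.float64))
        object.__setattr__(self, "assignment", np.asarray(self.assignment, dtype=np.intp))
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count does not match k")
        counts = np.bincount(self.assignment, minlength=self.k)
        if np.any(counts == 0):
            raise ValueError("every centroid must have at least one assigned point")


@dataclass(frozen=True)
class NearestTwo:
    """Ordered indices of each point's two closest centroids."""

    first: np.ndarray
    second: np.ndarray

    def __post_init__(self):
        first = np.asarray(self.first, dtype=np.intp)
        second = np.asarray(self.second, dtype=np.intp)
        if first.shape != second.shape:
            raise ValueError("first/second must have equal length")
        if np.any(first == second):
            raise ValueError("a point's two nearest centroids must differ")
        object.__setattr__(self, "first", first)
        object.__setattr__(self, "second", second)

    def unordered_pairs(self) -> np.ndarray:
        """n x 2 array of sorted (low, high) centroid index pairs."""
        return np.sort(np.stack([self.first, self.second], axis=1), axis=1)


def nearest_two(points: np.ndarray, centroids: np.ndarray) -> NearestTwo:
    """Ordered two closest centroids per point, Euclidean metric.

    Ties are broken toward the lower centroid index, which makes the
    Hebbian counts (and hence the whole tree) reproducible.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    centroids = np.atleast_2d(np.asarray(centroids, dtype=np.float64))
    if centroids.shape[0] < 2:
        raise ValueError("nearest_two requires at least 2 centroids")
    if points.shape[1] != centroids.shape[1]:
        raise ValueError("points and centroids must share dimensionality")
    dist = cdist(points, centroids)
    # stable argsort == lexicographic (distance, centroid index) order
    order = np.argsort(dist, axis=1, kind="stable")
    return NearestTwo(first=order[:, 0], second=order[:, 1])


def fit_quantization(X: ExpressionMatrix, k: int, seed: int = 0) -> Quantization:
    """k-means quantization of the expression matrix.

    Uses k-means++ initialisation with 10 restarts under a fixed seed; the
    returned assignment is re-derived with the deterministic nearest-centroid
    tie-break so that ``assignment[i] == nearest_two(X, centroids).first[i]``.
    """
    if not isinstance(X, ExpressionMatrix):
        X = ExpressionMatrix(np.asarray(X))
    if k < 2 or k > X.n:
        raise ValueError(f"k must satisfy 2 <= k <= n (= {X.n}); got {k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                random_state=int(seed) % (2**31), algorithm="lloyd")
    km.fit(X.values)
    centroids = km.cluster_centers_
    assignment = nearest_two(X.values, centroids).first
    counts = np.bincount(assignment, minlength=k)
    if np.any(counts == 0):
        # exact-tie reassignment emptied a cluster; fall back to sklearn labels
        assignment = km.labels_.astype(np.intp)
    return Quantization(centroids=centroids, assignment=assignment, k=k)
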