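"""Embedding quality metrics comparing high-dimensional data to a 2-D view.

Eight metrics in three families:

* local — adjusted Rand index between k-means clusterings of the two
  spaces, and k-nearest-neighbour preservation;
* global — Pearson and Spearman correlation between pairwise distances,
  with the high-dimensional distance either Euclidean or geodesic
  (shortest paths on a Euclidean-weighted symmetric kNN graph);
* Voronoi — the fraction of points lying in the "correct" first- or
  second-order Voronoi region, where the low-dimensional seeds are the
  per-cluster means of the embedded points.

Neighbourhood-sized metrics are swept over k = 10..100 (step 10) and
averaged, reported as an AUC.  The module accepts any externally produced
embedding, so competitor methods can be scored with the same code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Callable, Dict, Iterable, Sequence

import numpy as np
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr, spearmanr
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors, kneighbors_graph

from .quantization import nearest_two

__all__ = [
    "MetricsReport",
    "DEFAULT_K_GRID",
    "ari_clustering_agreement",
    "knn_preservation",
    "distance_correlations",
    "voronoi_agreement",
    "auc_over_k",
    "relative_scores",
    "evaluate_embedding",
    "report_table",
]

DEFAULT_K_GRID = tuple(range(10, 101, 10))


@dataclass(frozen=True)
class MetricsReport:
    """The eight-metric summary for one embedding of one dataset."""

    ari_auc: float
    knn_auc: float
    pearson_euclidean: float
    spearman_euclidean: float
    pearson_geodesic: float
    spearman_geodesic: float
    voronoi1_auc: float
    voronoi2_auc: float

    def as_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def mean(self) -> float:
        """Arithmetic mean over the eight metrics (the 'All' aggregate)."""
        return float(np.mean(list(self.as_dict().values())))


def _as_matrix(X) -> np.ndarray:
    X = getattr(X, "values", X)
    return np.asarray(X, dtype=np.float64)


def _check_aligned(X_high, X_low):
    X_high, X_low = _as_matrix(X_high), _as_matrix(X_low)
    if X_high.shape[0] != X_low.shape[0]:
        raise ValueError("high- and low-dimensional matrices must be row-aligned")
    return X_high, X_low


def ari_clustering_agreement(X_high, X_low, k: int, seed: int = 0) -> float:
    """ARI between independent k-means clusterings of the two spaces."""
    X_high, X_low = _check_aligned(X_high, X_low)
    if not 2 <= k <= X_high.shape[0]:
        raise ValueError(f"k must be in [2, n]; got {k}")
    rs = int(seed) % (2**31)
    labels_high = KMeans(n_clusters=k, n_init=10, random_state=rs).fit_predict(X_high)
    labels_low = KMeans(n_clusters=k, n_init=10, random_state=rs).fit_predict(X_low)
    return float(adjusted_rand_score(labels_high, labels_low))


def _knn_indices(X: np.ndarray, k: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    return nn.kneighbors(X, return_distance=False)[:, 1:]  # drop self


def knn_preservation(X_high, X_low, k: int) -> float:
    """Mean fraction of each point's k nearest neighbours shared by both spaces."""
    X_high, X_low = _check_aligned(X_high, X_low)
    n = X_high.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, n-1]; got {k}")
    high = _knn_indices(X_high, k)
    low = _knn_indices(X_low, k)
    overlap = np.fromiter(
        (np.intersect1d(high[i], low[i], assume_unique=True).size for i in range(n)),
        dtype=float,
        count=n,
    )
    return float(overlap.mean() / k)


def _geodesic_matrix(X: np.ndarray, idx: np.ndarray, knn_k: int) -> np.ndarray:
    """Shortest-path distances among ``X[idx]`` on the symmetric kNN graph of X."""
    graph = kneighbors_graph(X, n_neighbors=min(knn_k, X.shape[0] - 1), mode="distance")
    graph = graph.maximum(graph.T)  # symmetrise
    dist = shortest_path(graph, method="D", directed=False, indices=idx)
    return dist[:, idx]


def distance_correlations(
    X_high,
    X_low,
    high_metric: str = "euclidean",
    *,
    knn_k: int = 15,
    subsample: int = 1000,
    subsample_threshold: int = 3000,
    full: bool = False,
    seed: int = 0,
):
    """(Pearson, Spearman) correlation over all unordered pairwise distances.

    The low-dimensional distance is always Euclidean; the high-dimensional
    one is Euclidean or geodesic on the kNN graph.  For n above
    ``subsample_threshold`` a seeded subsample of points is used unless
    ``full`` is set.  Degenerate (zero-variance or empty) distance sets
    are reported as correlation 0 with a warning; geodesic pairs that are
    disconnected in the kNN graph are excluded.
    """
    if high_metric not in ("euclidean", "geodesic"):
        raise ValueError("high_metric must be 'euclidean' or 'geodesic'")
    X_high, X_low = _check_aligned(X_high, X_low)
    n = X_high.shape[0]
    if not full and n > subsample_threshold:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=subsample, replace=False))
    else:
        idx = np.arange(n)
    d_low = pdist(X_low[idx])
    if high_metric == "euclidean":
        d_high = pdist(X_high[idx])
    else:
        full_matrix = _geodesic_matrix(X_high, idx, knn_k)
        iu = np.triu_indices(len(idx), 1)
        d_high = full_matrix[iu]
        connected = np.isfinite(d_high)
        d_high, d_low = d_high[connected], d_low[connected]
    if d_high.size < 2 or np.ptp(d_high) == 0 or np.ptp(d_low) == 0:
        warnings.warn("degenerate pairwise distances; correlation undefined, reporting 0",
                      stacklevel=2)
        return 0.0, 0.0
    return float(pearsonr(d_high, d_low).statistic), float(spearmanr(d_high, d_low).statistic)


def voronoi_agreement(X_high, X_low, k: int, order: int = 1, seed: int = 0) -> float:
    """Fraction of points in the correct (first or second order) Voronoi cell.

    k-means runs in high dimension; the low-dimensional seeds are the
    per-cluster means of the embedded points.  Order 1 compares nearest
    seeds; order 2 compares the unordered nearest-two sets — for the
    training k this is exactly the quantity the push-pull loss optimises.
    """
    X_high, X_low = _check_aligned(X_high, X_low)
    if not 2 <= k <= X_high.shape[0]:
        raise ValueError(f"k must be in [2, n]; got {k}")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    # tol=0 runs Lloyd to strict convergence so labels are exactly the
    # nearest-centre assignment and centres are exactly the cluster means;
    # only then is the identity embedding a true fixed point of the metric.
    km = KMeans(n_clusters=k, n_init=10, tol=0, max_iter=500,
                random_state=int(seed) % (2**31)).fit(X_high)
    labels = km.labels_
    present = np.unique(labels)
    # seeds exist only for clusters that are non-empty (sklearn guarantees all)
    seeds = np.stack([X_low[labels == c].mean(axis=0) for c in present])
    if order == 1:
        nearest_low = present[np.argmin(
            ((X_low[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2), axis=1
        )]
        return float(np.mean(nearest_low == labels))
    pair_high = nearest_two(X_high, km.cluster_centers_).unordered_pairs()
    pair_low = present[nearest_two(X_low, seeds).unordered_pairs()]
    pair_low = np.sort(pair_low, axis=1)
    return float(np.mean(np.all(pair_high == pair_low, axis=1)))


def auc_over_k(
    metric_fn: Callable[[int], float], k_grid: Iterable[int] = DEFAULT_K_GRID
) -> float:
    """Mean of a metric over the neighbourhood-size grid (normalised AUC)."""
    values = [metric_fn(int(k)) for k in k_grid]
    if not values:
        raise ValueError("k_grid must be non-empty")
    return float(np.mean(values))


def relative_scores(
    raw_scores: Dict[str, float], higher_is_better: bool = True
) -> Dict[str, float]:
    """Scale scores so the best method gets 100 and others are proportional."""
    if not raw_scores:
        raise ValueError("at least one method is required")
    values = np.array(list(raw_scores.values()), dtype=float)
    if np.all(values == 0):
        raise ValueError("relative scores undefined when every score is 0")
    if higher_is_better:
        best = values.max()
        return {m: 100.0 * s / best for m, s in raw_scores.items()}
    best = values.min()
    return {m: 100.0 * best / s for m, s in raw_scores.items()}


def evaluate_embedding(
    X_high,
    X_low,
    *,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    seed: int = 0,
    geodesic_knn: int = 15,
    full_distances: bool = False,
) -> MetricsReport:
    """Compute the full eight-metric report for one embedding."""
    X_high, X_low = _check_aligned(X_high, X_low)
    n = X_high.shape[0]
    grid = [int(k) for k in k_grid if 2 <= k <= n - 1]
    if not grid:
        raise ValueError("k_grid contains no feasible neighbourhood sizes")
    pe, se = distance_correlations(
        X_high, X_low, "euclidean", full=full_distances, seed=seed
    )
    pg, sg = distance_correlations(
        X_high, X_low, "geodesic", knn_k=geodesic_knn, full=full_distances, seed=seed
    )
    return MetricsReport(
        ari_auc=auc_over_k(lambda k: ari_clustering_agreement(X_high, X_low, k, seed), grid),
        knn_auc=auc_over_k(lambda k: knn_preservation(X_high, X_low, k), grid),
        pearson_euclidean=pe,
        spearman_euclidean=se,
        pearson_geodesic=pg,
        spearman_geodesic=sg,
        voronoi1_auc=auc_over_k(lambda k: voronoi_agreement(X_high, X_low, k, 1, seed), grid),
        voronoi2_auc=auc_over_k(lambda k: voronoi_agreement(X_high, X_low, k, 2, seed), grid),
    )


def report_table(reports: Dict[str, MetricsReport]) -> "pd.DataFrame":  # noqa: F821
    """One row per method: the eight metrics plus their arithmetic mean."""
    import pandas as pd

    rows = {name: {**r.as_dict(), "mean": r.mean()} for name, r in reports.items()}
    return pd.DataFrame.from_dict(rows, orient="index")
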