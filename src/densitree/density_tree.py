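"""Density tree extraction: Hebbian edge weights and the maximum spanning tree.

Every data point "votes" for the edge between its two nearest centroids.
The vote count of an edge estimates the mass of the data density over the
corresponding second-order Voronoi region, so the maximum spanning tree
over these counts runs through dense regions of the data — unlike the
Euclidean-distance MST, which may shortcut through empty space.  For
developing cell populations the dense regions are the plausible
trajectories, which is exactly what the tree is meant to capture.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .quantization import ExpressionMatrix, Quantization, nearest_two

__all__ = [
    "EdgeWeights",
    "DensityTree",
    "hebbian_weights",
    "maximum_spanning_tree",
    "geodesic_distances",
    "degree_two_centroids",
    "prune_for_overlay",
    "build_density_tree",
    "tree_from_edges",
]


@dataclass(frozen=True)
class EdgeWeights:
    """Symmetric k x k matrix of per-edge data-point counts (zero diagonal)."""

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(counts < 0):
            raise ValueError("edge counts must be non-negative")
        if not np.array_equal(counts, counts.T):
            raise ValueError("edge counts must be symmetric")
        if np.any(np.diag(counts) != 0):
            raise ValueError("edge counts must have a zero diagonal")
        object.__setattr__(self, "counts", counts)

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    def total(self) -> int:
        """Sum of counts over unordered pairs (= number of data points)."""
        return int(self.counts.sum() // 2)


@dataclass(frozen=True)
class DensityTree:
    """A spanning tree over centroids with its provenance and derived maps."""

    edges: Tuple[Tuple[int, int], ...]  # k-1 unordered (low, high) pairs
    weights: EdgeWeights
    geodesic: np.ndarray  # k x k integer edge-count distances
    degree: np.ndarray  # per-centroid tree degree

    @property
    def k(self) -> int:
        return self.weights.k

    def total_weight(self) -> int:
        return int(sum(self.weights.counts[a, b] for a, b in self.edges))

    def leaves(self) -> np.ndarray:
        return np.flatnonzero(self.degree == 1)


def hebbian_weights(X, Q) -> EdgeWeights:
    """Count, per centroid pair, the points whose two nearest centroids they are.

    ``Q`` may be a fitted :class:`Quantization` or a raw centroid matrix.
    """
    data = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=np.float64)
    centroids = Q.centroids if isinstance(Q, Quantization) else np.asarray(Q, dtype=np.float64)
    k = centroids.shape[0]
    if data.ndim != 2 or data.shape[1] != centroids.shape[1]:
        raise ValueError("data dimensionality does not match the centroids")
    counts = np.zeros((k, k), dtype=np.int64)
    if data.shape[0] > 0:
        pairs = nearest_two(data, centroids).unordered_pairs()
        np.add.at(counts, (pairs[:, 0], pairs[:, 1]), 1)
        counts += counts.T
    return EdgeWeights(counts=counts)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def maximum_spanning_tree(W: EdgeWeights) -> DensityTree:
    """Maximum spanning tree of the complete centroid graph under Hebbian weights.

    Kruskal's algorithm on edges sorted by (descending weight, ascending
    index pair), so ties are resolved deterministically.  Zero-weight edges
    stay in the candidate set — the complete graph is always connected — but
    any accepted zero-weight edge marks a connection with no data support
    and is reported with a warning.
    """
    k = W.k
    if k < 2:
        raise ValueError("need at least 2 centroids for a spanning tree")
    iu, ju = np.triu_indices(k, 1)
    w = W.counts[iu, ju]
    order = np.lexsort((ju, iu, -w))  # weight desc, then (i, j) asc
    uf = _UnionFind(k)
    edges: List[Tuple[int, int]] = []
    unsupported: List[Tuple[int, int]] = []
    for idx in order:
        a, b = int(iu[idx]), int(ju[idx])
        if uf.union(a, b):
            edges.append((a, b))
            if w[idx] == 0:
                unsupported.append((a, b))
            if len(edges) == k - 1:
                break
    if unsupported:
        warnings.warn(
            "density tree forced through zero-weight edges (no data support): "
            f"{unsupported}",
            stacklevel=2,
        )
    geodesic = geodesic_distances(edges, k)
    degree = np.zeros(k, dtype=np.intp)
    for a, b in edges:
        degree[a] += 1
        degree[b] += 1
    return DensityTree(edges=tuple(edges), weights=W, geodesic=geodesic, degree=degree)


def geodesic_distances(edges, k: int | None = None) -> np.ndarray:
    """All-pairs path lengths (in edges) on a tree, by BFS from every vertex."""
    if isinstance(edges, DensityTree):
        k, edges = edges.k, edges.edges
    if k is None:
        raise ValueError("vertex count k is required with a raw edge list")
    adjacency: List[List[int]] = [[] for _ in range(k)]
    for a, b in edges:
        adjacency[a].append(b)
        adjacency[b].append(a)
    if len(edges) != k - 1:
        raise ValueError("input must be a tree (exactly k-1 edges)")
    geo = np.full((k, k), -1, dtype=np.int64)
    for source in range(k):
        geo[source, source] = 0
        queue = deque([source])
        while queue:
            u = queue.popleft()
            for v in adjacency[u]:
                if geo[source, v] < 0:
                    geo[source, v] = geo[source, u] + 1
                    queue.append(v)
    if np.any(geo < 0):
        raise ValueError("edge set is disconnected; not a spanning tree")
    return geo


def degree_two_centroids(T: DensityTree) -> List[Tuple[int, int, int]]:
    """Centroids with exactly two tree neighbours, as (centroid, n1, n2).

    These are the interior points of branches — the sites where the cosine
    straightness penalty applies.  Ordered by centroid index; neighbours in
    ascending index order.
    """
    neighbours: List[List[int]] = [[] for _ in range(T.k)]
    for a, b in T.edges:
        neighbours[a].append(b)
        neighbours[b].append(a)
    result = []
    for c in range(T.k):
        if len(neighbours[c]) == 2:
            n1, n2 = sorted(neighbours[c])
            result.append((c, n1, n2))
    return result


def prune_for_overlay(T: DensityTree, min_count: int = 100) -> Tuple[Tuple[int, int], ...]:
    """Tree edges whose Hebbian count strictly exceeds ``min_count``.

    Presentation-layer filter only (used when superimposing the tree on an
    embedding); the losses always see the full tree.
    """
    if min_count < 0:
        raise ValueError("min_count must be non-negative")
    return tuple((a, b) for a, b in T.edges if T.weights.counts[a, b] > min_count)


def build_density_tree(X: ExpressionMatrix, Q: Quantization) -> DensityTree:
    """Hebbian counting followed by the maximum spanning tree."""
    return maximum_spanning_tree(hebbian_weights(X, Q))


def tree_from_edges(edges, k: int, weights: EdgeWeights | None = None) -> DensityTree:
    """Assemble a :class:`DensityTree` from an explicit edge list.

    Convenience constructor for known topologies (tests, external trees);
    missing weights default to a unit count per edge.
    """
    edges = tuple((min(a, b), max(a, b)) for a, b in edges)
    if weights is None:
        counts = np.zeros((k, k), dtype=np.int64)
        for a, b in edges:
            counts[a, b] = counts[b, a] = 1
        weights = EdgeWeights(counts=counts)
    geodesic = geodesic_distances(edges, k)
    degree = np.zeros(k, dtype=np.intp)
    for a, b in edges:
        degree[a] += 1
        degree[b] += 1
    return DensityTree(edges=edges, weights=weights, geodesic=geodesic, degree=degree)
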