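"""Loss terms that bias the autoencoder bottleneck toward the density tree.

Four terms are combined:

* reconstruction — mean squared error of the decoded points, the ordinary
  autoencoder objective;
* push-pull — moves each embedded point toward the low-dimensional
  centroids of its *correct* pair (the two nearest centroids in input
  space) and away from its *currently* nearest pair in embedding space,
  each contribution normalised by the correct pair's separation (which
  prevents the trivial minimum at a collapsed embedding) and weighted by
  the geodesic tree distance of the current pair (so mistakes that jump
  between branches count more than mistakes within one branch);
* compactness — the pull term alone, squeezing points onto the segment
  between their correct centroids (per-point minimum 1, attained there);
* cosine — a straightness penalty, one minus the mean cosine of the turn
  angle at every degree-2 centroid of the tree, measured on
  embedding-space centroids.

All terms are implemented once, over the reverse-mode autodiff tensors,
so the same code path serves evaluation and training.  Embedding-space
centroids are per-cluster means of embedded points, and gradients flow
both through the points and through those means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .density_tree import DensityTree, degree_two_centroids
from .quantization import ExpressionMatrix, NearestTwo, nearest_two

__all__ = [
    "EPS",
    "LossWeights",
    "EmbeddingState",
    "reconstruction_loss",
    "push_pull_loss",
    "naive_push_pull_loss",
    "compactness_loss",
    "cosine_loss",
    "total_loss",
]

#: Floor applied to every distance denominator and cosine norm; coincident
#: centroids therefore yield large but finite loss values, never a fault.
EPS = 1e-8


@dataclass(frozen=True)
class LossWeights:
    """Relative importance of the four loss terms."""

    lambda_rec: float = 1.0
    lambda_push_pull: float = 1.0
    lambda_comp: float = 1.0
    lambda_cos: float = 50.0

    def __post_init__(self):
        values = (self.lambda_rec, self.lambda_push_pull, self.lambda_comp, self.lambda_cos)
        if not all(np.isfinite(v) and v >= 0 for v in values):
            raise ValueError("loss weights must be finite and non-negative")


@dataclass
class EmbeddingState:
    """Everything the tree-bias losses need about a 2-D embedding.

    ``correct_pair`` is a property of the data (two nearest centroids in
    input space) and is fixed per dataset; ``current_pair`` is the two
    nearest embedding-space centroids of each embedded point and must be
    recomputed whenever the embedding moves.
    """

    H: np.ndarray  # n x 2 embedding coordinates
    emb_centroids: np.ndarray  # k x 2 per-cluster means of H
    current_pair: NearestTwo
    correct_pair: NearestTwo
    assignment: np.ndarray | None = field(default=None)

    @classmethod
    def from_embedding(
        cls,
        H: np.ndarray,
        assignment: np.ndarray,
        k: int,
        correct_pair: NearestTwo,
    ) -> "EmbeddingState":
        H = np.asarray(H, dtype=np.float64)
        centroids = ad.segment_mean(ad.constant(H), assignment, k).value
        return cls(
            H=H,
            emb_centroids=centroids,
            current_pair=nearest_two(H, centroids),
            correct_pair=correct_pair,
            assignment=np.asarray(assignment, dtype=np.intp),
        )


# ---------------------------------------------------------------------------
# differentiable internals (operate on Tensors, return scalar Tensors)
# ---------------------------------------------------------------------------

def _row_norms(t: Tensor) -> Tensor:
    """Row-wise Euclidean norms, floored at EPS so gradients stay finite."""
    return ((t * t).sum(axis=1)).clip_min(EPS * EPS).sqrt()


def _pair_ratio(H: Tensor, cent: Tensor, pair: NearestTwo, denom: Tensor) -> Tensor:
    """((||h - c_a|| + ||h - c_b||) / denom) per point."""
    ca = ad.gather_rows(cent, pair.first)
    cb = ad.gather_rows(cent, pair.second)
    return (_row_norms(H - ca) + _row_norms(H - cb)) / denom


def _correct_separation(cent: Tensor, correct: NearestTwo) -> Tensor:
    c1 = ad.gather_rows(cent, correct.first)
    c2 = ad.gather_rows(cent, correct.second)
    return _row_norms(c1 - c2)


def push_pull_terms(
    H: Tensor,
    cent: Tensor,
    current: NearestTwo,
    correct: NearestTwo,
    geo_weight: np.ndarray,
) -> Tensor:
    """Geodesic-weighted normalised push-pull loss as a scalar Tensor."""
    denom = _correct_separation(cent, correct)
    push = -(_pair_ratio(H, cent, current, denom) ** 2)
    pull = _pair_ratio(H, cent, correct, denom) ** 2
    return (ad.constant(geo_weight) * (push + pull)).mean()


def naive_push_pull_terms(
    H: Tensor, cent: Tensor, current: NearestTwo, correct: NearestTwo
) -> Tensor:
    """Unnormalised push-pull (reference variant; shrinks under collapse)."""
    one = Tensor(np.ones(H.shape[0]))
    push = -(_pair_ratio(H, cent, current, one) ** 2)
    pull = _pair_ratio(H, cent, correct, one) ** 2
    return (push + pull).mean()


def compactness_terms(H: Tensor, cent: Tensor, correct: NearestTwo) -> Tensor:
    denom = _correct_separation(cent, correct)
    return (_pair_ratio(H, cent, correct, denom) ** 2).mean()


def cosine_terms(cent: Tensor, chain_sites: Sequence[Tuple[int, int, int]]) -> Tensor:
    """1 - mean cosine of turn angles at degree-2 centroids.

    Empty ``chain_sites`` (e.g. a star-shaped tree) yields 0: with no
    interior branch points there is nothing to straighten.
    """
    if len(chain_sites) == 0:
        return Tensor(0.0)
    sites = np.asarray(chain_sites, dtype=np.intp)
    c = ad.gather_rows(cent, sites[:, 0])
    n1 = ad.gather_rows(cent, sites[:, 1])
    n2 = ad.gather_rows(cent, sites[:, 2])
    v1 = c - n1
    v2 = n2 - c
    cos = (v1 * v2).sum(axis=1) / (_row_norms(v1) * _row_norms(v2)).clip_min(EPS)
    return 1.0 - cos.mean()


def reconstruction_terms(X: Tensor, X_hat: Tensor) -> Tensor:
    diff = X - X_hat
    return (diff * diff).sum(axis=1).mean()


# ---------------------------------------------------------------------------
# public evaluation API (floats in, floats out)
# ---------------------------------------------------------------------------

def reconstruction_loss(X, X_hat) -> float:
    """Mean squared Euclidean reconstruction error (1/N) sum ||x - x_hat||^2."""
    X = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=np.float64)
    X_hat = np.asarray(X_hat, dtype=np.float64)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    return float(reconstruction_terms(ad.constant(X), ad.constant(X_hat)).value)


def _geo_weight(S: EmbeddingState, T: DensityTree) -> np.ndarray:
    return T.geodesic[S.current_pair.first, S.current_pair.second].astype(np.float64)


def push_pull_loss(S: EmbeddingState, T: DensityTree) -> float:
    """Geodesic-weighted push-pull loss of an embedding state.

    Zero exactly when every point's nearest embedding-centroid pair matches
    its input-space pair; then the push and pull terms cancel pointwise.
    """
    return float(
        push_pull_terms(
            ad.constant(S.H),
            ad.constant(S.emb_centroids),
            S.current_pair,
            S.correct_pair,
            _geo_weight(S, T),
        ).value
    )


def naive_push_pull_loss(S: EmbeddingState) -> float:
    """Unnormalised reference variant; decreases when the embedding collapses."""
    return float(
        naive_push_pull_terms(
            ad.constant(S.H), ad.constant(S.emb_centroids), S.current_pair, S.correct_pair
        ).value
    )


def compactness_loss(S: EmbeddingState) -> float:
    """Mean squared (sum of distances to correct pair / pair separation); >= 1."""
    return float(
        compactness_terms(
            ad.constant(S.H), ad.constant(S.emb_centroids), S.correct_pair
        ).value
    )


def cosine_loss(S: EmbeddingState, chain_sites: Sequence[Tuple[int, int, int]] | DensityTree) -> float:
    """Branch-straightness penalty in [0, 2] over degree-2 tree centroids."""
    if isinstance(chain_sites, DensityTree):
        chain_sites = degree_two_centroids(chain_sites)
    return float(cosine_terms(ad.constant(S.emb_centroids), chain_sites).value)


def total_loss(components: Sequence[float], W: LossWeights) -> float:
    """Weighted combination; components ordered (rec, push-pull, comp, cos)."""
    rec, push_pull, comp, cos = components
    return (
        W.lambda_rec * rec
        + W.lambda_push_pull * push_pull
        + W.lambda_comp * comp
        + W.lambda_cos * cos
    )
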