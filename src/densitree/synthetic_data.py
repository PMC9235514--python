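"""Tree-structured toy data with ground-truth branch labels.

The generator emulates the statistical shape of branching differentiation
data: a smooth random-walk skeleton embedded in high-dimensional space,
with points spread evenly along the branches and perturbed by isotropic
Gaussian noise.  Two layouts are available:

* ``backbone`` — one long backbone branch plus side branches whose
  origins are sampled uniformly along it (the layout of the benchmark-scale
  toy experiment: 10 000 points, 100 dimensions, backbone + 9 branches);
* ``star`` — all branches emanate from a common origin, giving a tree
  whose leaf count equals the branch count (the classic three-armed
  example used throughout the tests).

Branch directions are mutually orthogonalised where the ambient dimension
allows (evenly spaced angles in 2-D), which keeps branch separation well
above the noise scale so that the density-tree topology of the generated
data is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .quantization import ExpressionMatrix

__all__ = [
    "ToyTreeSpec",
    "generate_tree_data",
    "generate_fixture_suite",
    "toy_benchmark_spec",
    "three_branch_spec",
    "lyre_data",
]


@dataclass(frozen=True)
class ToyTreeSpec:
    """Parameters of the branching-tree generator.

    noise_sd is the per-coordinate standard deviation of the additive
    Gaussian noise; with unit step size and the default walk smoothness it
    keeps points within a small fraction of a branch length of the skeleton.
    """

    n_points: int = 10_000
    n_dims: int = 100
    n_branches: int = 9
    branch_length: int = 60
    noise_sd: float = 0.3
    seed: int = 0
    step_size: float = 1.0
    momentum: float = 0.8
    curvature: float = 0.0
    layout: str = "backbone"

    def __post_init__(self):
        if self.layout not in ("backbone", "star"):
            raise ValueError("layout must be 'backbone' or 'star'")
        if self.n_dims < 2:
            raise ValueError("n_dims must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.branch_length < 1 or self.step_size <= 0:
            raise ValueError("branch_length >= 1 and step_size > 0 required")
        if not 0 <= self.momentum <= 1:
            raise ValueError("momentum must be in [0, 1]")
        if self.n_branches < 0:
            raise ValueError("n_branches must be >= 0")
        if self.n_points < self.total_branches:
            raise ValueError("need at least one point per branch")

    @property
    def total_branches(self) -> int:
        """Number of labelled branches (backbone counts as one)."""
        if self.layout == "backbone":
            return self.n_branches + 1
        if self.n_branches < 2:
            raise ValueError("star layout needs n_branches >= 2")
        return self.n_branches


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    if norm == 0:
        v = np.zeros_like(v)
        v[0] = 1.0
        return v
    return v / norm


def _random_walk(start, direction, n_steps, spec: ToyTreeSpec, rng) -> np.ndarray:
    """Smooth random walk: a momentum-filtered unit direction, optionally
    bent by a constant in-plane curvature (radians per step).

    Non-zero curvature turns every branch the same way, producing the
    pinwheel geometry in which adjacent branches approach each other in
    space while remaining connected only through the origin — the setting
    where a Euclidean-distance MST shortcuts across the gap but the
    density tree does not.
    """
    path = np.empty((n_steps + 1, spec.n_dims))
    path[0] = start
    w = _unit(np.asarray(direction, dtype=float))
    # in-plane normal for the curvature rotation (2-D: the left-hand normal)
    if spec.n_dims == 2:
        u = np.array([-w[1], w[0]])
    else:
        u = rng.standard_normal(spec.n_dims)
        u = _unit(u - (u @ w) * w)
    theta = spec.curvature
    for t in range(1, n_steps + 1):
        if theta != 0.0:
            w, u = (
                np.cos(theta) * w + np.sin(theta) * u,
                -np.sin(theta) * w + np.cos(theta) * u,
            )
        if spec.momentum < 1.0:
            w = _unit(spec.momentum * w + (1 - spec.momentum) * rng.standard_normal(spec.n_dims))
            u = _unit(u - (u @ w) * w)
        path[t] = path[t - 1] + spec.step_size * w
    return path


def _branch_directions(n: int, spec: ToyTreeSpec, rng) -> np.ndarray:
    d = spec.n_dims
    if d == 2:
        offset = rng.uniform(0, 2 * np.pi)
        angles = offset + 2 * np.pi * np.arange(n) / n
        return np.stack([np.cos(angles), np.sin(angles)], axis=1)
    if n <= d:  # mutually orthogonal starts guarantee separation
        q, _ = np.linalg.qr(rng.standard_normal((d, n)))
        return q.T * np.sign(rng.standard_normal(n))[:, None]
    return np.stack([_unit(rng.standard_normal(d)) for _ in range(n)])


def _sample_along(path: np.ndarray, m: int) -> np.ndarray:
    """m points spread evenly in arc length over a polyline."""
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = (np.arange(m) + 0.5) / m * cum[-1]
    out = np.empty((m, path.shape[1]))
    for j in range(path.shape[1]):
        out[:, j] = np.interp(targets, cum, path[:, j])
    return out


def generate_tree_data(spec: ToyTreeSpec) -> Tuple[ExpressionMatrix, np.ndarray]:
    """Sample a branching-tree dataset; returns (matrix, branch labels).

    Points are allocated to branches as evenly as possible (counts differ
    by at most one) and positioned uniformly along each branch's arc
    length before the noise is added.  Deterministic for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    paths = []
    if spec.layout == "backbone":
        backbone = _random_walk(
            np.zeros(spec.n_dims), rng.standard_normal(spec.n_dims), spec.branch_length, spec, rng
        )
        paths.append(backbone)
        if spec.n_branches > 0:
            origins = rng.integers(1, spec.branch_length, size=spec.n_branches)
            side_dirs = _branch_directions(spec.n_branches, spec, rng)
            for origin_idx, direction in zip(origins, side_dirs):
                tangent = _unit(backbone[origin_idx] - backbone[origin_idx - 1])
                direction = direction - (direction @ tangent) * tangent
                paths.append(
                    _random_walk(backbone[origin_idx], _unit(direction),
                                 spec.branch_length, spec, rng)
                )
    else:  # star: every branch starts at the origin
        for direction in _branch_directions(spec.n_branches, spec, rng):
            paths.append(
                _random_walk(np.zeros(spec.n_dims), direction, spec.branch_length, spec, rng)
            )

    n_branches = len(paths)
    base, extra = divmod(spec.n_points, n_branches)
    sizes = [base + (1 if i < extra else 0) for i in range(n_branches)]
    blocks, labels = [], []
    for label, (path, size) in enumerate(zip(paths, sizes)):
        points = _sample_along(path, size)
        if spec.noise_sd > 0:
            points = points + rng.normal(0.0, spec.noise_sd, size=points.shape)
        blocks.append(points)
        labels.append(np.full(size, label, dtype=np.intp))
    values = np.vstack(blocks)
    return ExpressionMatrix(values), np.concatenate(labels)


def toy_benchmark_spec(seed: int = 0, n_points: int = 10_000) -> ToyTreeSpec:
    """The benchmark-scale toy setting: backbone + 9 branches, 100 dimensions."""
    return ToyTreeSpec(n_points=n_points, n_dims=100, n_branches=9, seed=seed)


def three_branch_spec(
    n_points: int = 2000,
    n_dims: int = 50,
    noise_sd: float = 0.4,
    seed: int = 0,
    curvature: float = 0.0,
) -> ToyTreeSpec:
    """Three branches from a common origin — the standard small test bed."""
    return ToyTreeSpec(
        n_points=n_points,
        n_dims=n_dims,
        n_branches=3,
        branch_length=30,
        noise_sd=noise_sd,
        seed=seed,
        curvature=curvature,
        layout="star",
    )


def lyre_data(
    n_points: int = 600,
    noise_sd: float = 0.4,
    seed: int = 0,
    branch_length: int = 30,
    turn_deg: float = 80.0,
) -> Tuple[ExpressionMatrix, np.ndarray]:
    """Three 2-D branches from one origin, two of them curving together.

    Two arms start up-left and up-right and bend toward each other until
    their tips nearly meet; the third arm runs straight down.  The tip gap
    (about 3.5 units at the default turn, versus an along-branch centroid
    spacing of roughly twice that at k = 12) is the situation where a
    Euclidean-distance MST shortcuts across the gap although no data lie
    in it, while the density tree keeps the path through the junction.
    The tip gap stays well above 5x the default noise scale.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    base = ToyTreeSpec(
        n_points=n_points, n_dims=2, n_branches=3, branch_length=branch_length,
        noise_sd=noise_sd, seed=seed, momentum=1.0, layout="star",
    )
    turn = np.deg2rad(turn_deg) / branch_length
    arms = [
        (np.deg2rad(135.0), replace(base, curvature=-turn)),
        (np.deg2rad(45.0), replace(base, curvature=turn)),
        (np.deg2rad(270.0), replace(base, curvature=0.0)),
    ]
    base, extra = divmod(n_points, 3)
    sizes = [base + (1 if i < extra else 0) for i in range(3)]
    blocks, labels = [], []
    for label, ((angle, arm_spec), size) in enumerate(zip(arms, sizes)):
        direction = np.array([np.cos(angle), np.sin(angle)])
        path = _random_walk(np.zeros(2), direction, branch_length, arm_spec, rng)
        points = _sample_along(path, size)
        if noise_sd > 0:
            points = points + rng.normal(0.0, noise_sd, size=points.shape)
        blocks.append(points)
        labels.append(np.full(size, label, dtype=np.intp))
    return ExpressionMatrix(np.vstack(blocks)), np.concatenate(labels)


def generate_fixture_suite(seed: int = 0) -> Dict[str, Tuple[ExpressionMatrix, Optional[np.ndarray]]]:
    """Small named datasets used by the test suite (all <= 2000 points).

    * ``three_branch_2d`` — three noisy branches from one origin in 2-D,
      two of them curving toward each other (the lyre geometry);
    * ``three_branch_2d_clean`` — the same skeleton without noise;
    * ``rank2_linear`` — exactly rank-2 data a 2-D bottleneck can encode;
    * ``two_clusters`` — two well-separated Gaussian blobs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    fixtures: Dict[str, Tuple[ExpressionMatrix, Optional[np.ndarray]]] = {}
    fixtures["three_branch_2d"] = lyre_data(n_points=600, noise_sd=0.4, seed=seed)
    fixtures["three_branch_2d_clean"] = lyre_data(n_points=600, noise_sd=0.0, seed=seed)
    loadings = rng.standard_normal((2, 20))
    scores = rng.standard_normal((500, 2)) * np.array([3.0, 1.0])
    fixtures["rank2_linear"] = (ExpressionMatrix(scores @ loadings), None)
    blob1 = rng.normal(0.0, 0.5, size=(200, 5))
    blob2 = rng.normal(0.0, 0.5, size=(200, 5)) + 8.0
    labels = np.repeat([0, 1], 200).astype(np.intp)
    fixtures["two_clusters"] = (ExpressionMatrix(np.vstack([blob1, blob2])), labels)
    return fixtures
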