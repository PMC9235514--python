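import numpy as np
import pytest

from densitree.density_tree import tree_from_edges
from densitree.losses import (
    EmbeddingState,
    LossWeights,
    compactness_loss,
    cosine_loss,
    naive_push_pull_loss,
    push_pull_loss,
    reconstruction_loss,
    total_loss,
)
from densitree.quantization import NearestTwo, nearest_two


def random_state(rng, n=40, k=6, dim=2):
    """A consistent random embedding state over k non-empty clusters."""
    assignment = np.concatenate([np.arange(k), rng.integers(0, k, n - k)])
    H = rng.standard_normal((n, dim)) * 3
    first = rng.integers(0, k, n)
    correct = NearestTwo(first=first, second=(first + rng.integers(1, k, n)) % k)
    state = EmbeddingState.from_embedding(H, assignment, k, correct)
    return state


class TestReconstruction:
    def test_perfect_reconstruction(self, rng):
        X = rng.standard_normal((10, 4))
        assert reconstruction_loss(X, X) == 0.0

    def test_hand_value(self):
        assert reconstruction_loss(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]])) == 25.0

    def test_quadratic_homogeneity(self, rng):
        X = rng.standard_normal((7, 3))
        R = rng.standard_normal((7, 3))
        assert reconstruction_loss(X, X + 2 * R) == pytest.approx(
            4 * reconstruction_loss(X, X + R)
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 2)), np.zeros((2, 3)))


def hand_state(extra_centroids=()):
    """1-D embedding, centroids 0,1,4(+extras), one point at h=3, correct pair (0,1)."""
    centroids = np.array([[0.0], [1.0], [4.0]] + [[c] for c in extra_centroids])
    H = np.array([[3.0]])
    return EmbeddingState(
        H=H,
        emb_centroids=centroids,
        current_pair=nearest_two(H, centroids),
        correct_pair=NearestTwo(first=[0], second=[1]),
    )


class TestPushPull:
    def test_hand_example_geodesic_one(self):
        # current pair is (4, 1): push = -((1+2)/1)^2 = -9, pull = ((3+2)/1)^2 = 25
        state = hand_state()
        T = tree_from_edges([(0, 1), (1, 2)], k=3)
        assert state.current_pair.first[0] == 2 and state.current_pair.second[0] == 1
        assert push_pull_loss(state, T) == pytest.approx(16.0, abs=1e-9)

    def test_linear_in_geodesic_weight(self):
        # far dummy centroids stretch the tree path of the current pair to 3 edges
        state = hand_state(extra_centroids=(100.0, 200.0))
        T = tree_from_edges([(0, 1), (1, 3), (3, 4), (4, 2)], k=5)
        assert T.geodesic[1, 2] == 3
        assert push_pull_loss(state, T) == pytest.approx(48.0, abs=1e-9)

    def test_zero_when_pairs_match(self, rng):
        T = tree_from_edges([(i, i + 1) for i in range(5)], k=6)
        for _ in range(25):
            state = random_state(rng)
            matched = EmbeddingState(
                H=state.H,
                emb_centroids=state.emb_centroids,
                current_pair=state.current_pair,
                correct_pair=state.current_pair,
            )
            assert abs(push_pull_loss(matched, T)) < 1e-9

    def test_batch_loss_non_negative(self, rng):
        T = tree_from_edges([(i, i + 1) for i in range(5)], k=6)
        for _ in range(10):
            assert push_pull_loss(random_state(rng), T) >= -1e-12


class TestCompactness:
    def test_on_segment_equals_one(self):
        centroids = np.array([[0.0, 0.0], [2.0, 0.0]])
        for x in (0.3, 1.0, 1.9):
            state = EmbeddingState(
                H=np.array([[x, 0.0]]),
                emb_centroids=centroids,
                current_pair=NearestTwo(first=[0], second=[1]),
                correct_pair=NearestTwo(first=[0], second=[1]),
            )
            assert compactness_loss(state) == pytest.approx(1.0, abs=1e-12)

    def test_hand_value_off_segment(self):
        state = EmbeddingState(
            H=np.array([[1.0, 1.0]]),
            emb_centroids=np.array([[0.0, 0.0], [2.0, 0.0]]),
            current_pair=NearestTwo(first=[0], second=[1]),
            correct_pair=NearestTwo(first=[0], second=[1]),
        )
        assert compactness_loss(state) == pytest.approx(2.0, abs=1e-12)

    def test_at_least_one_per_point(self, rng):
        # triangle inequality: the summed distances can never undercut the base
        for _ in range(20):
            centroids = rng.standard_normal((4, 2))
            state = EmbeddingState(
                H=rng.standard_normal((1, 2)) * 3,
                emb_centroids=centroids,
                current_pair=NearestTwo(first=[0], second=[1]),
                correct_pair=NearestTwo(first=[2], second=[3]),
            )
            assert compactness_loss(state) >= 1.0 - 1e-12


class TestCosine:
    def _state(self, centroids):
        centroids = np.asarray(centroids, dtype=float)
        return EmbeddingState(
            H=centroids[:1],
            emb_centroids=centroids,
            current_pair=NearestTwo(first=[0], second=[1]),
            correct_pair=NearestTwo(first=[0], second=[1]),
        )

    def test_straight_chain_is_zero(self):
        state = self._state([[0, 0], [1, 0], [2, 0], [3, 0]])
        sites = [(1, 0, 2), (2, 1, 3)]
        assert cosine_loss(state, sites) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_is_one(self):
        state = self._state([[0, 0], [1, 0], [1, 1]])
        assert cosine_loss(state, [(1, 0, 2)]) == pytest.approx(1.0, abs=1e-12)

    def test_empty_sites_zero(self):
        state = self._state([[0, 0], [1, 0]])
        assert cosine_loss(state, []) == 0.0

    def test_range(self, rng):
        for _ in range(20):
            state = random_state(rng, n=8, k=8)
            value = cosine_loss(state, [(1, 0, 2), (3, 2, 4)])
            assert 0.0 - 1e-12 <= value <= 2.0 + 1e-12


class TestScaleBehaviour:
    def test_normalized_losses_scale_invariant(self, rng):
        T = tree_from_edges([(i, i + 1) for i in range(5)], k=6)
        for scale in (0.1, 3.7):
            state = random_state(rng)
            scaled = EmbeddingState(
                H=state.H * scale,
                emb_centroids=state.emb_centroids * scale,
                current_pair=state.current_pair,
                correct_pair=state.correct_pair,
            )
            for fn in (lambda s: push_pull_loss(s, T), compactness_loss):
                a, b = fn(state), fn(scaled)
                assert abs(a - b) <= 1e-9 * max(1.0, abs(a))

    def test_naive_loss_shrinks_under_collapse(self, rng):
        # the anti-collapse rationale for the normalization
        for _ in range(10):
            state = random_state(rng)
            shrunk = EmbeddingState(
                H=state.H * 0.5,
                emb_centroids=state.emb_centroids * 0.5,
                current_pair=state.current_pair,
                correct_pair=state.correct_pair,
            )
            assert naive_push_pull_loss(shrunk) < naive_push_pull_loss(state)


class TestTotalLoss:
    def test_default_weights(self):
        assert LossWeights() == LossWeights(1.0, 1.0, 1.0, 50.0)
        assert total_loss((1, 2, 3, 0.1), LossWeights()) == pytest.approx(11.0)

    def test_zero_weights(self):
        assert total_loss((5, 5, 5, 5), LossWeights(0, 0, 0, 0)) == 0.0

    def test_rejects_negative_weight(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_rec=-1)
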