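"""Autoencoder architecture and the two-phase training procedure.

The network is a symmetric fully connected autoencoder with a 2-D
bottleneck used directly as the visualization coordinates.  Training has
two phases: reconstruction-only pretraining on shuffled minibatches (a
warm start), then full-batch finetuning under the combined tree-bias
loss.  Finetuning must be full-batch because the embedding-space
centroids are means over *all* embedded points of a cluster and are
recomputed, inside the graph, at every step.
"""

from __future__ import annotations

import json
import warnings
import zipfile
from dataclasses import dataclass, field
from io import BytesIO
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .density_tree import DensityTree, build_density_tree, degree_two_centroids
from .losses import (
    LossWeights,
    compactness_terms,
    cosine_terms,
    push_pull_terms,
    reconstruction_terms,
)
from .quantization import ExpressionMatrix, NearestTwo, Quantization, fit_quantization, nearest_two

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "Autoencoder",
    "build_network",
    "pretrain",
    "finetune",
    "embed",
    "fit_pipeline",
    "FitResult",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Layer plan for the symmetric autoencoder.

    Hidden layers wider than the input are dropped, so a 100-dimensional
    input with the default plan yields encoder dims 100 -> 32 -> 2.
    """

    input_dim: int
    hidden_dims: Tuple[int, ...] = (2048, 256, 32)
    bottleneck: int = 2

    def __post_init__(self):
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if any(h < 1 for h in self.hidden_dims) or self.bottleneck < 1:
            raise ValueError("layer dimensions must be positive")
        if self.bottleneck != 2:
            warnings.warn(
                "bottleneck != 2: embeddings will not be directly plottable",
                stacklevel=2,
            )

    def encoder_dims(self) -> List[int]:
        kept = [h for h in self.hidden_dims if h <= self.input_dim]
        return [self.input_dim, *kept, self.bottleneck]

    def decoder_dims(self) -> List[int]:
        return list(reversed(self.encoder_dims()))


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings for the two training phases (Adam throughout)."""

    pretrain_epochs: int = 150
    finetune_epochs: int = 150
    pretrain_lr: float = 2e-4
    finetune_lr: float = 1e-3
    pretrain_batch: int = 256
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        if self.pretrain_epochs < 0 or self.finetune_epochs < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.pretrain_lr <= 0 or self.finetune_lr <= 0:
            raise ValueError("learning rates must be > 0")
        if self.pretrain_batch < 1:
            raise ValueError("pretrain_batch must be >= 1")


class Autoencoder:
    """Fully connected encoder/decoder pair with shared parameter list.

    ReLU follows every layer except the final encoder layer (the 2-D
    bottleneck stays unconstrained) and the final decoder layer.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.encoder = self._init_layers(spec.encoder_dims(), rng)
        self.decoder = self._init_layers(spec.decoder_dims(), rng)

    @staticmethod
    def _init_layers(dims: Sequence[int], rng) -> List[Tuple[Tensor, Tensor]]:
        layers = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            bound = 1.0 / np.sqrt(fan_in)  # fan-based uniform init
            W = Tensor(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            b = Tensor(rng.uniform(-bound, bound, size=(fan_out,)))
            layers.append((W, b))
        return layers

    def parameters(self) -> List[Tensor]:
        return [p for layer in self.encoder + self.decoder for p in layer]

    @staticmethod
    def _forward(layers, x: Tensor) -> Tensor:
        for i, (W, b) in enumerate(layers):
            x = x @ W + b
            if i < len(layers) - 1:
                x = ad.relu(x)
        return x

    def encode(self, x: Tensor) -> Tensor:
        return self._forward(self.encoder, x)

    def decode(self, h: Tensor) -> Tensor:
        return self._forward(self.decoder, h)


def build_network(spec: NetworkSpec, seed: int = 0) -> Autoencoder:
    """Deterministically initialised autoencoder for the given layer plan."""
    return Autoencoder(spec, seed=seed)


class Adam:
    """Adam optimiser over a fixed parameter list."""

    def __init__(self, params: Sequence[Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            p.value = p.value - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _check_finite(value: float, phase: str, epoch: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(
            f"non-finite loss ({value}) during {phase} at epoch {epoch}; "
            "try a lower learning rate"
        )


def pretrain(net: Autoencoder, X: ExpressionMatrix, cfg: TrainConfig) -> List[float]:
    """Reconstruction-only minibatch warm start; returns per-epoch mean loss."""
    data = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=np.float64)
    n = data.shape[0]
    optimiser = Adam(net.parameters(), lr=cfg.pretrain_lr)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    trace: List[float] = []
    for epoch in range(cfg.pretrain_epochs):
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, cfg.pretrain_batch):
            batch = data[order[start : start + cfg.pretrain_batch]]
            x = ad.constant(batch)
            loss = reconstruction_terms(x, net.decode(net.encode(x)))
            optimiser.zero_grad()
            loss.backward()
            optimiser.step()
            total += float(loss.value) * batch.shape[0]
            seen += batch.shape[0]
        epoch_loss = total / seen
        _check_finite(epoch_loss, "pretraining", epoch)
        trace.append(epoch_loss)
    return trace


def finetune(
    net: Autoencoder,
    X: ExpressionMatrix,
    Q: Quantization,
    T: DensityTree,
    cfg: TrainConfig,
) -> Dict[str, List[float]]:
    """Full-batch finetuning under the combined tree-bias loss.

    Per epoch: encode everything, rebuild embedding-space centroids as
    per-cluster means inside the graph, recompute each point's currently
    nearest centroid pair, evaluate the four loss terms, and take one Adam
    step.  The input-space correct pairs and the geodesic matrix are fixed
    before the loop.  Returns per-epoch component traces.
    """
    data = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=np.float64)
    correct = nearest_two(data, Q.centroids)
    chain_sites = degree_two_centroids(T)
    weights = cfg.loss_weights
    optimiser = Adam(net.parameters(), lr=cfg.finetune_lr)
    x = ad.constant(data)
    trace: Dict[str, List[float]] = {
        "reconstruction": [], "push_pull": [], "compactness": [], "cosine": [], "total": []
    }
    for epoch in range(cfg.finetune_epochs):
        h = net.encode(x)
        x_hat = net.decode(h)
        cent = ad.segment_mean(h, Q.assignment, Q.k)
        current = nearest_two(h.value, cent.value)
        geo_weight = T.geodesic[current.first, current.second].astype(np.float64)

        rec = reconstruction_terms(x, x_hat)
        push_pull = push_pull_terms(h, cent, current, correct, geo_weight)
        comp = compactness_terms(h, cent, correct)
        cos = cosine_terms(cent, chain_sites)
        loss = (
            weights.lambda_rec * rec
            + weights.lambda_push_pull * push_pull
            + weights.lambda_comp * comp
            + weights.lambda_cos * cos
        )
        _check_finite(float(loss.value), "finetuning", epoch)
        optimiser.zero_grad()
        loss.backward()
        optimiser.step()

        trace["reconstruction"].append(float(rec.value))
        trace["push_pull"].append(float(push_pull.value))
        trace["compactness"].append(float(comp.value))
        trace["cosine"].append(float(cos.value))
        trace["total"].append(float(loss.value))
    return trace


def embed(net: Autoencoder, X) -> np.ndarray:
    """Deterministic forward pass through the encoder; rows align with X."""
    data = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=np.float64)
    if data.shape[1] != net.spec.input_dim:
        raise ValueError(
            f"input has {data.shape[1]} features, network expects {net.spec.input_dim}"
        )
    return net.encode(ad.constant(data)).value.copy()


@dataclass
class FitResult:
    """Everything a full pipeline run produces."""

    quantization: Quantization
    tree: DensityTree
    network: Autoencoder
    embedding: np.ndarray  # n x 2
    correct_pair: NearestTwo
    pretrain_trace: List[float]
    finetune_trace: Dict[str, List[float]]

    def embedding_centroids(self) -> np.ndarray:
        return ad.segment_mean(
            ad.constant(self.embedding), self.quantization.assignment, self.quantization.k
        ).value


def fit_pipeline(
    X: ExpressionMatrix,
    k: int = 50,
    cfg: TrainConfig | None = None,
    spec: NetworkSpec | None = None,
) -> FitResult:
    """Quantize, extract the density tree, pretrain, finetune, embed."""
    if not isinstance(X, ExpressionMatrix):
        X = ExpressionMatrix(np.asarray(X))
    cfg = cfg or TrainConfig()
    spec = spec or NetworkSpec(input_dim=X.d)
    if spec.input_dim != X.d:
        raise ValueError("network input_dim does not match data")
    Q = fit_quantization(X, k, seed=cfg.seed)
    T = build_density_tree(X, Q)
    net = build_network(spec, seed=cfg.seed)
    pre = pretrain(net, X, cfg)
    fine = finetune(net, X, Q, T, cfg)
    return FitResult(
        quantization=Q,
        tree=T,
        network=net,
        embedding=embed(net, X),
        correct_pair=nearest_two(X.values, Q.centroids),
        pretrain_trace=pre,
        finetune_trace=fine,
    )


def save_checkpoint(net: Autoencoder, path, extra: dict | None = None) -> None:
    """Write the network (layer plan + parameters) to a single zip archive.

    The archive holds a JSON manifest and one ``.npy`` entry per parameter,
    so a checkpoint restores bit-identical weights.
    """
    manifest = {
        "input_dim": net.spec.input_dim,
        "hidden_dims": list(net.spec.hidden_dims),
        "bottleneck": net.spec.bottleneck,
        "n_encoder_layers": len(net.encoder),
        "extra": extra or {},
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("manifest.json", json.dumps(manifest))
        for i, p in enumerate(net.parameters()):
            buf = BytesIO()
            np.save(buf, p.value)
            zf.writestr(f"param_{i}.npy", buf.getvalue())


def load_checkpoint(path) -> Autoencoder:
    with zipfile.ZipFile(path, "r") as zf:
        manifest = json.loads(zf.read("manifest.json"))
        spec = NetworkSpec(
            input_dim=manifest["input_dim"],
            hidden_dims=tuple(manifest["hidden_dims"]),
            bottleneck=manifest["bottleneck"],
        )
        net = Autoencoder(spec, seed=0)
        for i, p in enumerate(net.parameters()):
            p.value = np.load(BytesIO(zf.read(f"param_{i}.npy")))
    return net
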