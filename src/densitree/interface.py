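"""File I/O, run configuration and output writing.

Conventions: cells are rows everywhere; delimited matrices carry the cell
ids in the first column and feature ids in the header; MatrixMarket
inputs get synthetic ids; ``.h5ad`` files use the primary matrix unless a
layer is named.  A ``fit`` run writes every artefact needed to reproduce
and inspect it: the embedding, the tree edge list with Hebbian counts,
the geodesic matrix, per-epoch loss traces, a config snapshot, and
optionally the tree-overlay figure.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .density_tree import DensityTree, prune_for_overlay
from .losses import LossWeights
from .model import FitResult, NetworkSpec, TrainConfig
from .quantization import ExpressionMatrix

__all__ = ["RunConfig", "read_matrix", "write_matrix", "write_outputs", "export_tree"]

logger = logging.getLogger("densitree")

_DELIMITED = {"csv": ",", "tsv": "\t"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "tsv", "mtx", "h5ad"):
        return suffix
    if suffix in ("txt", "tab"):
        return "tsv"
    raise ValueError(f"cannot infer matrix format from extension: {path.name}")


def read_matrix(path, fmt: Optional[str] = None, layer: Optional[str] = None) -> ExpressionMatrix:
    """Load a cells-by-features matrix from CSV/TSV, MatrixMarket or H5AD."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or _infer_format(path)).lower()
    if fmt in _DELIMITED:
        frame = pd.read_csv(path, sep=_DELIMITED[fmt], index_col=0)
        values = frame.to_numpy(dtype=np.float64)
        if np.isnan(values).any():
            raise ValueError(f"{path.name}: matrix contains missing values")
        return ExpressionMatrix(values, row_ids=frame.index.astype(str),
                                col_ids=frame.columns.astype(str))
    if fmt == "mtx":
        from scipy.io import mmread

        values = np.asarray(mmread(path).todense(), dtype=np.float64)
        return ExpressionMatrix(values)
    if fmt == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        matrix = adata.layers[layer] if layer else adata.X
        if hasattr(matrix, "toarray"):
            matrix = matrix.toarray()
        return ExpressionMatrix(np.asarray(matrix, dtype=np.float64),
                                row_ids=adata.obs_names, col_ids=adata.var_names)
    raise ValueError(f"unknown matrix format: {fmt!r}")


def write_matrix(X: ExpressionMatrix, path, fmt: str = "csv") -> None:
    if fmt not in _DELIMITED:
        raise ValueError("write_matrix supports csv/tsv")
    pd.DataFrame(X.values, index=X.row_ids, columns=X.col_ids).to_csv(
        path, sep=_DELIMITED[fmt]
    )


@dataclass
class RunConfig:
    """Fully serialisable description of one ``fit`` run."""

    input: str = ""
    input_format: Optional[str] = None
    k: int = 50
    hidden_dims: tuple = (2048, 256, 32)
    bottleneck: int = 2
    train: TrainConfig = field(default_factory=TrainConfig)
    out_dir: str = "densitree_run"
    evaluate: bool = False
    overlay: bool = True
    prune_min_count: int = 100
    log1p: bool = False
    scale: bool = False

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["hidden_dims"] = list(self.hidden_dims)
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        train = data.pop("train", {})
        weights = train.pop("loss_weights", {})
        data["train"] = TrainConfig(**train, loss_weights=LossWeights(**weights))
        data["hidden_dims"] = tuple(data.get("hidden_dims", (2048, 256, 32)))
        return cls(**data)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def network_spec(self, input_dim: int) -> NetworkSpec:
        return NetworkSpec(input_dim=input_dim, hidden_dims=tuple(self.hidden_dims),
                           bottleneck=self.bottleneck)


def export_tree(T: DensityTree, tsv_path, graphml_path=None, min_count: int = 100) -> None:
    """Edge list TSV (u, v, hebbian_count, in_pruned_overlay) and GraphML."""
    pruned = set(prune_for_overlay(T, min_count))
    rows = [
        {"u": a, "v": b, "hebbian_count": int(T.weights.counts[a, b]),
         "in_pruned_overlay": (a, b) in pruned}
        for a, b in T.edges
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if graphml_path is not None:
        import networkx as nx

        graph = nx.Graph()
        graph.add_nodes_from(range(T.k))
        for a, b in T.edges:
            graph.add_edge(a, b, hebbian_count=int(T.weights.counts[a, b]),
                           in_pruned_overlay=(a, b) in pruned)
        nx.write_graphml(graph, graphml_path)


def plot_overlay(
    embedding: np.ndarray,
    emb_centroids: np.ndarray,
    T: DensityTree,
    path,
    labels: Optional[np.ndarray] = None,
    min_count: int = 100,
) -> None:
    """Scatter of the embedding with pruned tree edges between centroids.

    Edge darkness scales with the Hebbian count, so denser connections
    draw darker.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if labels is not None:
        ax.scatter(embedding[:, 0], embedding[:, 1], s=4, c=labels, cmap="tab10", alpha=0.6)
    else:
        ax.scatter(embedding[:, 0], embedding[:, 1], s=4, color="steelblue", alpha=0.6)
    edges = prune_for_overlay(T, min_count)
    if edges:
        max_count = max(int(T.weights.counts[a, b]) for a, b in edges)
        for a, b in edges:
            shade = 0.25 + 0.75 * T.weights.counts[a, b] / max_count
            ax.plot(
                emb_centroids[[a, b], 0], emb_centroids[[a, b], 1],
                color=(0, 0, 0, shade), linewidth=1.5,
            )
    ax.scatter(emb_centroids[:, 0], emb_centroids[:, 1], s=18, c="black", marker="s")
    ax.set_xlabel("bottleneck 1")
    ax.set_ylabel("bottleneck 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_outputs(
    result: FitResult,
    X: ExpressionMatrix,
    out_dir,
    config: Optional[RunConfig] = None,
    labels: Optional[np.ndarray] = None,
    overlay: bool = True,
    prune_min_count: int = 100,
) -> Dict[str, Path]:
    """Write all run artefacts into ``out_dir``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}

    embedding = pd.DataFrame(result.embedding, columns=["x", "y"])
    embedding.insert(0, "cell_id", X.row_ids)
    embedding.to_csv(out / "embedding.csv", index=False)
    written["embedding"] = out / "embedding.csv"

    export_tree(result.tree, out / "tree_edges.tsv", out / "tree.graphml", prune_min_count)
    written["tree_edges"] = out / "tree_edges.tsv"
    written["tree_graphml"] = out / "tree.graphml"

    pd.DataFrame(result.tree.geodesic).to_csv(out / "geodesic.tsv", sep="\t", index=False)
    written["geodesic"] = out / "geodesic.tsv"

    trace_rows = [
        {"phase": "pretrain", "epoch": i, "reconstruction": v, "push_pull": np.nan,
         "compactness": np.nan, "cosine": np.nan, "total": v}
        for i, v in enumerate(result.pretrain_trace)
    ]
    fine = result.finetune_trace
    trace_rows += [
        {"phase": "finetune", "epoch": i,
         "reconstruction": fine["reconstruction"][i], "push_pull": fine["push_pull"][i],
         "compactness": fine["compactness"][i], "cosine": fine["cosine"][i],
         "total": fine["total"][i]}
        for i in range(len(fine["total"]))
    ]
    pd.DataFrame(trace_rows).to_csv(out / "loss_trace.tsv", sep="\t", index=False)
    written["loss_trace"] = out / "loss_trace.tsv"

    if config is not None:
        config.save(out / "config.yaml")
        written["config"] = out / "config.yaml"

    if overlay:
        plot_overlay(result.embedding, result.embedding_centroids(), result.tree,
                     out / "overlay.png", labels=labels, min_count=prune_min_count)
        written["overlay"] = out / "overlay.png"

    with open(out / "run_info.json", "w") as fh:
        json.dump(
            {"n_cells": X.n, "n_features": X.d, "k": result.quantization.k,
             "tree_total_weight": result.tree.total_weight(),
             "n_leaves": int(result.tree.leaves().size)},
            fh, indent=2,
        )
    written["run_info"] = out / "run_info.json"
    return written
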