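"""Graph encoders and the dot-product link predictor.

Two encoders are provided: a spectral graph convolutional network (GCN)
using symmetric-normalized propagation with self-loops, and a
GraphSAGE-style encoder with mean neighborhood aggregation.  Both are
bias-free stacks of ``n_layers`` linear layers with ReLU between layers and
a linear output; the collaboration score between two nodes is the inner
product of their final embeddings.

The graphs handled here are desk-scale (hundreds to a few thousand
affiliations), so everything is dense numpy; forward and backward passes
are written out explicitly, which keeps the model fully deterministic per
seed and free of heavyweight framework dependencies.
"""

from __future__ import annotations


import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

Pair = tuple[int, int]


@dataclass
class ModelConfig:
    encoder: str = "gcn"            # "gcn" or "sage"
    n_layers: int = 2
    hidden_dim: int = 128
    use_edge_weights: bool = True   # weighted adjacency enters propagation

    def __post_init__(self) -> None:
        if self.encoder not in ("gcn", "sage"):
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if self.n_layers < 1 or self.hidden_dim < 1:
            raise ValueError("n_layers and hidden_dim must be >= 1")


@dataclass
class ModelState:
    """Per-layer weight matrices, keyed by name.

    gcn layers hold ``W{l}``; sage layers hold ``W_self{l}`` and
    ``W_nbr{l}``.  Shapes chain input width -> hidden -> ... -> hidden.
    """

    params: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def copy(self) -> "ModelState":
        return ModelState({k: v.copy() for k, v in self.params.items()}, self.seed)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_state(config: ModelConfig, in_dim: int, seed: int = 0) -> ModelState:
    """Seeded Glorot-uniform initialization of all layer weights."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    dims = [in_dim] + [config.hidden_dim] * config.n_layers
    for l in range(config.n_layers):
        if config.encoder == "gcn":
            params[f"W{l}"] = _glorot(rng, dims[l], dims[l + 1])
        else:
            params[f"W_self{l}"] = _glorot(rng, dims[l], dims[l + 1])
            params[f"W_nbr{l}"] = _glorot(rng, dims[l], dims[l + 1])
    return ModelState(params=params, seed=seed)


def normalize_adjacency(a: np.ndarray, use_edge_weights: bool = True) -> np.ndarray:
    """Symmetric GCN propagation operator D^{-1/2} (A + I) D^{-1/2}.

    ``a`` must be symmetric with zero diagonal.  With ``use_edge_weights``
    off the adjacency is binarized first, so scaling all weights leaves the
    result unchanged.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {a.shape}")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if a.shape[0] == 0:
        return a.copy()
    if not use_edge_weights:
        a = (a > 0).astype(float)
    a_hat = a + np.eye(a.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_hat.sum(axis=1))
    return a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def mean_aggregator(a: np.ndarray) -> np.ndarray:
    """Row-normalized adjacency D^{-1} A (neighbor mean; zero for isolates)."""
    a = np.asarray(a, dtype=float)
    deg = a.sum(axis=1)
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    return a * inv[:, None]


def propagation_operator(a: np.ndarray, config: ModelConfig) -> np.ndarray:
    """The message-passing matrix the configured encoder consumes."""
    if config.encoder == "gcn":
        return normalize_adjacency(a, config.use_edge_weights)
    a = np.asarray(a, dtype=float)
    if not config.use_edge_weights:
        a = (a > 0).astype(float)
    return mean_aggregator(a)


def _forward(
    x: np.ndarray, p: np.ndarray, state: ModelState, config: ModelConfig
) -> tuple[np.ndarray, list]:
    """Forward pass returning (H, cache for backprop)."""
    h = x
    cache = []
    for l in range(config.n_layers):
        last = l == config.n_layers - 1
        if config.encoder == "gcn":
            ph = p @ h
            z = ph @ state.params[f"W{l}"]
            cache.append(("gcn", l, ph, z))
        else:
            ph = p @ h
            z = h @ state.params[f"W_self{l}"] + ph @ state.params[f"W_nbr{l}"]
            cache.append(("sage", l, h, ph, z))
        h = z if last else np.maximum(z, 0.0)
    return h, cache


def _backward(
    d_h: np.ndarray, p: np.ndarray, cache: list, state: ModelState, config: ModelConfig
) -> dict[str, np.ndarray]:
    """Gradients of the loss w.r.t. every weight, given dL/dH at the output."""
    grads: dict[str, np.ndarray] = {}
    for entry in reversed(cache):
        last = entry[1] == config.n_layers - 1
        if entry[0] == "gcn":
            _, l, ph, z = entry
            dz = d_h if last else d_h * (z > 0)
            grads[f"W{l}"] = ph.T @ dz
            d_h = p.T @ (dz @ state.params[f"W{l}"].T)
        else:
            _, l, h_in, ph, z = entry
            dz = d_h if last else d_h * (z > 0)
            grads[f"W_self{l}"] = h_in.T @ dz
            grads[f"W_nbr{l}"] = ph.T @ dz
            d_h = dz @ state.params[f"W_self{l}"].T + p.T @ (
                dz @ state.params[f"W_nbr{l}"].T
            )
    return grads


def encode(
    x: np.ndarray, p: np.ndarray, state: ModelState, config: ModelConfig
) -> np.ndarray:
    """Encode node features into embeddings H (N x hidden_dim).

    ``p`` is the propagation operator for the configured encoder (see
    :func:`propagation_operator`): symmetric-normalized adjacency with
    self-loops for gcn, row-normalized adjacency for sage.
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    if x.shape[0] != p.shape[0]:
        raise ValueError(
            f"feature rows ({x.shape[0]}) and operator size ({p.shape[0]}) differ"
        )
    first = next(iter(state.params.values()))
    if first.shape[0] != x.shape[1]:
        raise ValueError(
            f"input width {x.shape[1]} does not match first layer {first.shape[0]}"
        )
    h, _ = _forward(x, p, state, config)
    return h


def dot_score(h_u: np.ndarray, h_i: np.ndarray) -> float:
    """Collaboration score: inner product of two embeddings (symmetric)."""
    h_u = np.asarray(h_u, dtype=float)
    h_i = np.asarray(h_i, dtype=float)
    if h_u.shape != h_i.shape:
        raise ValueError(f"embedding shapes differ: {h_u.shape} vs {h_i.shape}")
    return float(h_u @ h_i)


def score_edges(h: np.ndarray, edges: Sequence[Pair]) -> np.ndarray:
    """Dot scores for a list of node-index pairs, order-preserving."""
    h = np.asarray(h, dtype=float)
    if len(edges) == 0:
        return np.zeros(0)
    idx = np.asarray(edges, dtype=int)
    if idx.min() < 0 or idx.max() >= h.shape[0]:
        raise IndexError(f"edge endpoint out of range for {h.shape[0]} nodes")
    return np.einsum("ij,ij->i", h[idx[:, 0]], h[idx[:, 1]])


def save_state(state: ModelState, config: ModelConfig, path: str | Path) -> None:
    """Save weights + config as one archive; round-trips bit-exactly."""
    blob = {f"param:{k}": v for k, v in state.params.items()}
    blob["__meta__"] = np.frombuffer(
        json.dumps({"config": asdict(config), "seed": state.seed}).encode(), dtype=np.uint8
    )
    np.savez(path, **blob)


def load_state(path: str | Path) -> tuple[ModelState, ModelConfig]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {
            k[len("param:"):]: data[k] for k in data.files if k.startswith("param:")
        }
    return ModelState(params=params, seed=meta["seed"]), ModelConfig(**meta["config"])
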