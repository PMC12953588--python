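"""Node attribute fusion into fixed-width feature matrices.

Each affiliation's attributes — how active it is (trial count), where it
runs trials (country profile) and what it tests (intervention category
profile) — are fused into one feature vector per node.  Free-text
attributes go through a pluggable :class:`EmbeddingProvider`; the default
provider is a local deterministic feature-hashing encoder, so the package
never needs a network call.  An external embedding service can be plugged
in behind the same contract, with an on-disk cache keyed by text hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .graph_build import CollabGraph, dominant


@dataclass
class EmbeddingProvider:
    """Contract for text -> dense vector encoders.

    ``embed`` must be deterministic for a fixed (text, provider config) and
    return a finite vector of length ``dim``.
    """

    name: str
    dim: int
    embed: Callable[[str], np.ndarray]


@dataclass
class FeatureMatrix:
    """N x d real matrix aligned to the graph's stable node order."""

    values: np.ndarray
    node_order: list[str]

    @property
    def dim(self) -> int:
        return int(self.values.shape[1]) if self.values.ndim == 2 else 0

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, row in zip(self.node_order, self.values):
                fh.write(name + "\t" + "\t".join(f"{x:.8g}" for x in row) + "\n")


def _tokenize(text: str) -> list[str]:
    out, cur = [], []
    for ch in text.lower():
        if ch.isalnum():
            cur.append(ch)
        elif cur:
            out.append("".join(cur))
            cur = []
    if cur:
        out.append("".join(cur))
    return out


def default_text_encoder(dim: int = 32, seed: int = 0) -> EmbeddingProvider:
    """Deterministic feature-hashing text encoder.

    Tokens are hashed (salted by ``seed``) into ``dim`` buckets with +/-1
    signs and the result is L2-normalized; the empty string maps to the
    zero vector.  This is the offline stand-in for an external embedding
    API: it has no semantics, but identical texts get identical vectors and
    distinct attribute values get near-orthogonal ones, which is what the
    downstream fusion and tests rely on.
    """
    if dim < 1:
        raise ValueError(f"embedding dim must be >= 1, got {dim}")
    salt = str(seed).encode()

    def embed(text: str) -> np.ndarray:
        vec = np.zeros(dim)
        tokens = _tokenize(text)
        for tok in tokens:
            h = hashlib.blake2b(tok.encode(), key=salt, digest_size=8).digest()
            val = int.from_bytes(h, "big")
            vec[(val >> 1) % dim] += 1.0 if val & 1 else -1.0
        norm = np.linalg.norm(vec)
        if norm == 0 and tokens:
            # tokens cancelled pairwise in one bucket; fall back to a
            # whole-text bucket so non-empty text keeps a unit embedding
            h = hashlib.blake2b(text.encode(), key=salt, digest_size=8).digest()
            vec[int.from_bytes(h, "big") % dim] = 1.0
            norm = 1.0
        return vec / norm if norm > 0 else vec

    return EmbeddingProvider(name=f"hash{dim}-s{seed}", dim=dim, embed=embed)


def cached_provider(inner: EmbeddingProvider, cache_path: str | Path) -> EmbeddingProvider:
    """Wrap a provider with a JSON on-disk cache keyed by text hash.

    Intended for expensive external providers; the default hashing encoder
    does not need it.
    """
    cache_path = Path(cache_path)
    cache: dict[str, list[float]] = {}
    if cache_path.exists():
        cache = json.loads(cache_path.read_text())

    def embed(text: str) -> np.ndarray:
        key = hashlib.sha256(text.encode()).hexdigest()
        if key not in cache:
            cache[key] = [float(x) for x in inner.embed(text)]
            cache_path.write_text(json.dumps(cache))
        return np.asarray(cache[key])

    return EmbeddingProvider(name=inner.name + "+cache", dim=inner.dim, embed=embed)


def _projection(in_dim: int, out_dim: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.standard_normal((in_dim, out_dim)) / np.sqrt(in_dim)


def fuse_node_features(
    graph: CollabGraph,
    provider: EmbeddingProvider | None = None,
    out_dim: int = 128,
    seed: int = 0,
) -> FeatureMatrix:
    """Fuse per-node attributes into the encoder input matrix X.

    Per node the following blocks are concatenated:

    * ``log(1 + trial_count)`` — activity level, log-damped because trial
      counts span orders of magnitude;
    * provider embedding of the dominant country (mode of the country
      tally, ties broken lexicographically);
    * the normalized intervention-category histogram in the graph's fixed
      category order (sums to 1, or all-zero for nodes with no recorded
      interventions);
    * provider embedding of the dominant intervention category.

    If the concatenation width differs from ``out_dim`` a seeded random
    linear projection maps it there.  Rows follow the graph's stable node
    order, so the output is invariant to record insertion order.
    """
    provider = provider or default_text_encoder(dim=32, seed=seed)
    order = graph.node_order
    if not order:
        return FeatureMatrix(values=np.zeros((0, out_dim)), node_order=[])
    categories = graph.categories()
    rows = []
    for name in order:
        info = graph.nodes[name]
        hist = np.array(
            [float(info.intervention_counts.get(c, 0)) for c in categories]
        )
        total = hist.sum()
        if total > 0:
            hist = hist / total
        row = np.concatenate([
            [np.log1p(info.trial_count)],
            provider.embed(dominant(info.country_counts)),
            hist,
            provider.embed(dominant(info.intervention_counts)),
        ])
        rows.append(row)
    x = np.vstack(rows)
    if x.shape[1] != out_dim:
        x = x @ _projection(x.shape[1], out_dim, seed)
    if not np.all(np.isfinite(x)):
        raise ValueError("fused feature matrix contains non-finite entries")
    return FeatureMatrix(values=x, node_order=list(order))


def structure_only_features(
    graph: CollabGraph, out_dim: int = 128, seed: int = 0
) -> FeatureMatrix:
    """Attribute-free ablation features: node identity + activity only.

    Each node gets a seeded random projection of its one-hot identity plus
    the log trial count — the information a purely structural encoder
    starts from, with no country or intervention signal.  Used to measure
    what attribute fusion adds.
    """
    order = graph.node_order
    n = len(order)
    if n == 0:
        return FeatureMatrix(values=np.zeros((0, out_dim)), node_order=[])
    x = np.concatenate(
        [
            np.array([[np.log1p(graph.nodes[name].trial_count)] for name in order]),
            np.eye(n),
        ],
        axis=1,
    )
    if x.shape[1] != out_dim:
        x = x @ _projection(x.shape[1], out_dim, seed)
    return FeatureMatrix(values=x, node_order=list(order))
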