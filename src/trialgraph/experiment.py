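"""Link-prediction experiments: edge splitting, negative sampling, training
and evaluation.

The experimental protocol mirrors standard practice for collaboration-link
prediction: positive edges are observed collaborations, negatives are
sampled non-adjacent pairs at a 1:1 ratio, and evaluation reports ROC AUC,
F1 and Accuracy@K over repeated independent runs.  Two split strategies are
provided — a temporal split (train on collaborations registered up to a
cutoff year, test on pairs first appearing the following year) and a random
edge split that keeps every node attached to at least one training edge.

Leakage control: with the temporal split, the graph, node attributes and
features are built exclusively from train-period records; test-year trials
contribute nothing to counts or features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import f1_score as _sk_f1_score

from .exceptions import SamplingError, SplitError, TrainingError
from .features import FeatureMatrix, default_text_encoder, fuse_node_features, structure_only_features
from .gnn_core import (
    ModelConfig,
    ModelState,
    encode,
    init_state,
    propagation_operator,
    score_edges,
)
from .graph_build import CollabGraph, build_graph, edge_key
from .registry_io import TrialRecord

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


# ---------------------------------------------------------------------------
# Edge splits


@dataclass
class EdgeSplit:
    """Disjoint train/validation/test positive and negative edge sets.

    Invariants: positives of different roles are pairwise disjoint, every
    negative set is disjoint from every positive set, no pair appears in two
    roles, and each negative set matches its positive set 1:1 in size.
    """

    train_pos: list[Pair] = field(default_factory=list)
    train_neg: list[Pair] = field(default_factory=list)
    val_pos: list[Pair] = field(default_factory=list)
    val_neg: list[Pair] = field(default_factory=list)
    test_pos: list[Pair] = field(default_factory=list)
    test_neg: list[Pair] = field(default_factory=list)

    def roles(self) -> dict[str, list[Pair]]:
        return {
            "train_pos": self.train_pos, "train_neg": self.train_neg,
            "val_pos": self.val_pos, "val_neg": self.val_neg,
            "test_pos": self.test_pos, "test_neg": self.test_neg,
        }

    def validate(self, require_negatives: bool = True) -> None:
        sets = {name: set(pairs) for name, pairs in self.roles().items()}
        for name, pairs in self.roles().items():
            if len(sets[name]) != len(pairs):
                raise SplitError(f"{name} contains duplicate pairs")
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                overlap = sets[a] & sets[b]
                if overlap:
                    raise SplitError(
                        f"{a} and {b} share {len(overlap)} pair(s), e.g. {next(iter(overlap))}"
                    )
        if require_negatives:
            for role in ("train", "val", "test"):
                np_, nn = len(sets[f"{role}_pos"]), len(sets[f"{role}_neg"])
                if np_ != nn:
                    raise SplitError(f"{role}: {np_} positives vs {nn} negatives (need 1:1)")


def _pair_first_years(records: Sequence[TrialRecord]) -> dict[Pair, int]:
    first: dict[Pair, int] = {}
    for r in records:
        if r.year is None:
            continue
        for a, b in combinations(dict.fromkeys(r.affiliations), 2):
            k = edge_key(a, b)
            if k not in first or r.year < first[k]:
                first[k] = r.year
    return first


def temporal_split(
    records: Sequence[TrialRecord], graph: CollabGraph, cutoff_year: int
) -> EdgeSplit:
    """Temporal positives: train = pairs supported up to the cutoff year,
    test = pairs first appearing in cutoff_year + 1.

    Pairs first appearing later than cutoff + 1 are ignored; test pairs
    whose endpoints never collaborated before the cutoff (absent from the
    training graph) cannot be scored and are dropped.  Negatives are filled
    separately with :func:`sample_negatives`.
    """
    dated = [r for r in records if r.year is not None]
    if not dated:
        raise SplitError(
            "no records carry a registration year; use the random split instead"
        )
    first = _pair_first_years(dated)
    train_pos = sorted(k for k, y in first.items() if y <= cutoff_year)
    test_pos = sorted(
        k for k, y in first.items()
        if y == cutoff_year + 1 and k[0] in graph.nodes and k[1] in graph.nodes
    )
    return EdgeSplit(train_pos=train_pos, test_pos=test_pos)


def random_split_with_isolated(
    graph: CollabGraph, test_fraction: float, rng_seed: int = 0
) -> EdgeSplit:
    """Random edge split that never strands a node.

    Edges are shuffled by seed and moved to the test set until the target
    fraction is reached, but an edge is only eligible if both endpoints
    keep at least one other training edge — so no node is isolated from the
    training graph.  Edges incident to degree-1 nodes are therefore always
    training edges.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0,1), got {test_fraction}")
    edges = sorted(graph.edges)
    if len(edges) < 2:
        raise SplitError(f"need at least 2 edges to split, have {len(edges)}")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(edges))
    quota = int(round(test_fraction * len(edges)))
    train_deg: dict[str, int] = {}
    for u, v in edges:
        train_deg[u] = train_deg.get(u, 0) + 1
        train_deg[v] = train_deg.get(v, 0) + 1
    test: list[Pair] = []
    test_set: set[Pair] = set()
    for i in order:
        if len(test) >= quota:
            break
        u, v = edges[i]
        if train_deg[u] > 1 and train_deg[v] > 1:
            test.append((u, v))
            test_set.add((u, v))
            train_deg[u] -= 1
            train_deg[v] -= 1
    train = [e for e in edges if e not in test_set]
    return EdgeSplit(train_pos=train, test_pos=sorted(test))


def carve_validation(split: EdgeSplit, fraction: float, rng_seed: int) -> EdgeSplit:
    """Move a seeded random fraction of train positives into the validation
    role (early stopping monitors their loss)."""
    rng = np.random.default_rng(rng_seed)
    pos = list(split.train_pos)
    n_val = int(round(fraction * len(pos)))
    idx = set(rng.choice(len(pos), size=n_val, replace=False).tolist()) if n_val else set()
    split.val_pos = sorted(pos[i] for i in idx)
    split.train_pos = [p for i, p in enumerate(pos) if i not in idx]
    return split


def sample_negatives(
    graph: CollabGraph,
    positives_to_match: Sequence[Pair],
    forbidden: set[Pair] | None = None,
    rng_seed: int = 0,
) -> list[Pair]:
    """Uniform sample of non-adjacent node pairs, without replacement.

    Returns exactly ``len(positives_to_match)`` pairs drawn from the
    unordered non-edges of the graph, excluding ``forbidden``; deterministic
    per seed.
    """
    n_needed = len(positives_to_match)
    if n_needed == 0:
        return []
    forbidden = forbidden or set()
    nodes = graph.node_order
    pool = [
        k for a, b in combinations(nodes, 2)
        if (k := edge_key(a, b)) not in graph.edges and k not in forbidden
    ]
    if len(pool) < n_needed:
        raise SamplingError(
            f"need {n_needed} negative pairs but only {len(pool)} non-edges "
            f"are available (deficit {n_needed - len(pool)})"
        )
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(len(pool), size=n_needed, replace=False)
    return [pool[i] for i in idx]


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    l2: float = 1e-5
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    n_repeats: int = 10

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.max_epochs, self.patience, self.n_repeats) <= 0:
            raise ValueError("learning_rate, max_epochs, patience, n_repeats must be positive")
        if self.l2 < 0:
            raise ValueError("l2 must be non-negative")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")


def _bce_with_logits(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy on logits; returns (loss, dL/ds)."""
    softplus = np.maximum(scores, 0.0) + np.log1p(np.exp(-np.abs(scores)))
    loss = float(np.mean(softplus - labels * scores))
    sig = 1.0 / (1.0 + np.exp(-scores))
    return loss, (sig - labels) / scores.size


def _pairs_to_indices(pairs: Sequence[Pair], order: Sequence[str]) -> np.ndarray:
    index = {n: i for i, n in enumerate(order)}
    if not pairs:
        return np.zeros((0, 2), dtype=int)
    return np.asarray([(index[u], index[v]) for u, v in pairs], dtype=int)


def training_adjacency(
    graph: CollabGraph,
    train_pos: Sequence[Pair],
    scale_by_intervention: bool = True,
) -> np.ndarray:
    """Adjacency restricted to training positives (message edges).

    Weights come from the full graph's edge info — collaboration count,
    optionally scaled by (1 + intervention_norm) so intervention-heavy ties
    propagate up to twice as strongly without any edge vanishing — but
    validation/test positive pairs carry no weight, so no label information
    leaks into message passing.
    """
    order = graph.node_order
    index = {n: i for i, n in enumerate(order)}
    a = np.zeros((len(order), len(order)))
    for u, v in train_pos:
        e = graph.edges.get(edge_key(u, v))
        w = float(e.collab_count) if e else 1.0
        if e and scale_by_intervention:
            w *= 1.0 + e.intervention_norm
        a[index[u], index[v]] = w
        a[index[v], index[u]] = w
    return a


class _Adam:
    """Plain Adam with decoupled-from-nothing L2 added to the gradients."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, l2: float):
        self.lr, self.l2 = lr, l2
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in params:
            g = grads[k] + self.l2 * params[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1 ** self.t)
            v_hat = self.v[k] / (1 - self.beta2 ** self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(
    x: FeatureMatrix | np.ndarray,
    graph: CollabGraph,
    split: EdgeSplit,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    scale_by_intervention: bool = True,
) -> tuple[ModelState, list[dict]]:
    """Fit the encoder by binary cross-entropy on dot-product edge scores.

    Positive (observed) and negative (sampled) training pairs get labels
    1/0; the loss is BCE of sigmoid(s_uv).  Adam with L2 regularization;
    early stopping monitors the validation loss (train loss if no
    validation edges) and the best-epoch state is returned together with
    the per-epoch loss history.
    """
    from .gnn_core import _backward, _forward  # internal fwd/bwd pair

    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    split.validate(require_negatives=False)
    order = graph.node_order
    xv = x.values if isinstance(x, FeatureMatrix) else np.asarray(x, dtype=float)
    a = training_adjacency(graph, split.train_pos, scale_by_intervention)
    p = propagation_operator(a, model_config)

    tr_idx = np.vstack([
        _pairs_to_indices(split.train_pos, order),
        _pairs_to_indices(split.train_neg, order),
    ])
    tr_labels = np.concatenate([
        np.ones(len(split.train_pos)), np.zeros(len(split.train_neg))
    ])
    va_idx = np.vstack([
        _pairs_to_indices(split.val_pos, order),
        _pairs_to_indices(split.val_neg, order),
    ])
    va_labels = np.concatenate([
        np.ones(len(split.val_pos)), np.zeros(len(split.val_neg))
    ])

    state = init_state(model_config, xv.shape[1], seed=train_config.seed)
    opt = _Adam(state.params, train_config.learning_rate, train_config.l2)
    best_state, best_loss, best_epoch = state.copy(), math.inf, -1
    history: list[dict] = []
    for epoch in range(train_config.max_epochs):
        h, cache = _forward(xv, p, state, model_config)
        scores = np.einsum("ij,ij->i", h[tr_idx[:, 0]], h[tr_idx[:, 1]])
        loss, dscore = _bce_with_logits(scores, tr_labels)
        if not math.isfinite(loss):
            raise TrainingError(f"non-finite training loss at epoch {epoch}")
        d_h = np.zeros_like(h)
        np.add.at(d_h, tr_idx[:, 0], dscore[:, None] * h[tr_idx[:, 1]])
        np.add.at(d_h, tr_idx[:, 1], dscore[:, None] * h[tr_idx[:, 0]])
        grads = _backward(d_h, p, cache, state, model_config)
        opt.step(state.params, grads)

        if len(va_idx):
            hv, _ = _forward(xv, p, state, model_config)
            v_scores = np.einsum("ij,ij->i", hv[va_idx[:, 0]], hv[va_idx[:, 1]])
            monitor, _ = _bce_with_logits(v_scores, va_labels)
        else:
            monitor = loss
        history.append({"epoch": epoch, "train_loss": loss, "val_loss": monitor})
        if monitor < best_loss:
            best_loss, best_epoch = monitor, epoch
            best_state = state.copy()
        elif epoch - best_epoch >= train_config.patience:
            break
    return best_state, history


# ---------------------------------------------------------------------------
# Metrics


def auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """ROC AUC as the rank statistic: the probability that a random
    positive outranks a random negative, ties counted 1/2."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("auc requires non-empty positive and negative scores")
    ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = ranks[: pos.size].sum()
    return float((pos_ranks - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def f1(scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5) -> float:
    """F1 = 2PR/(P+R) with predictions sigmoid(score) >= threshold; 0 when
    precision + recall is 0."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    preds = (1.0 / (1.0 + np.exp(-scores)) >= threshold).astype(int)
    return float(_sk_f1_score(labels, preds, zero_division=0))


def accuracy_at_k(
    rankings: Mapping[str, Sequence[str]],
    relevants: Mapping[str, set],
    k: int | float,
    mode: str = "normalized",
) -> float:
    """Top-K hit metric over users.

    literal mode: mean over users of |Rel_i ∩ Rec_i(k)| — the raw hit
    count.  normalized mode (reporting default): each user's hits are
    divided by min(k, |Rel_i|), giving a value in [0, 1] that is monotone
    in k and comparable across users.  Users with no relevant items are
    skipped with a warning.
    """
    if mode not in ("literal", "normalized"):
        raise ValueError(f"unknown mode {mode!r}")
    if not math.isinf(k) and k < 1:
        raise ValueError("k must be >= 1")
    if set(rankings) != set(relevants):
        raise ValueError("rankings and relevants must cover the same users")
    total, n_users = 0.0, 0
    for user, ranked in rankings.items():
        rel = relevants[user]
        if not rel:
            logger.warning("accuracy_at_k: user %s has no relevant items, skipped", user)
            continue
        top = list(ranked) if math.isinf(k) else list(ranked)[: int(k)]
        hits = len(rel.intersection(top))
        if mode == "literal":
            total += hits
        else:
            total += hits / min(k, len(rel))
        n_users += 1
    return total / n_users if n_users else 0.0


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass
class ExperimentConfig:
    """End-to-end pipeline configuration (build -> features -> split ->
    negatives -> train -> evaluate)."""

    split: str = "temporal"            # "temporal" or "random"
    cutoff_year: int = 2021
    test_fraction: float = 0.2         # random split only
    feature_mode: str = "fused"        # "fused" or "structure"
    embed_dim: int = 32                # text-encoder width
    feature_dim: int = 128
    val_fraction: float = 0.1
    k_max: int = 10
    acc_mode: str = "normalized"
    candidate_pool: int = 50           # sampled negatives per test user
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)


@dataclass
class MetricsReport:
    """Per-repeat metrics plus mean and standard deviation."""

    per_repeat: list[dict]
    auc_mean: float
    auc_sd: float
    f1_mean: float
    f1_sd: float
    acc_at_k_mean: dict[int, float]
    acc_mode: str
    n_repeats: int

    @classmethod
    def from_repeats(cls, rows: list[dict], acc_mode: str) -> "MetricsReport":
        aucs = np.array([r["auc"] for r in rows])
        f1s = np.array([r["f1"] for r in rows])
        ks = sorted(rows[0]["acc_at_k"])
        acc_mean = {
            k: float(np.mean([r["acc_at_k"][k] for r in rows])) for k in ks
        }
        return cls(
            per_repeat=rows,
            auc_mean=float(aucs.mean()), auc_sd=float(aucs.std(ddof=0)),
            f1_mean=float(f1s.mean()), f1_sd=float(f1s.std(ddof=0)),
            acc_at_k_mean=acc_mean, acc_mode=acc_mode, n_repeats=len(rows),
        )

    def to_json(self) -> str:
        import json

        def keyfix(d):
            if isinstance(d, dict):
                return {str(k): keyfix(v) for k, v in d.items()}
            if isinstance(d, list):
                return [keyfix(v) for v in d]
            return d

        return json.dumps(keyfix(asdict(self)), sort_keys=True, indent=2)

    def to_csv(self) -> str:
        ks = sorted(self.acc_at_k_mean)
        header = "repeat,auc,f1," + ",".join(f"acc@{k}" for k in ks)
        lines = [header]
        for i, r in enumerate(self.per_repeat):
            cells = [str(i), repr(r["auc"]), repr(r["f1"])]
            cells += [repr(r["acc_at_k"][k]) for k in ks]
            lines.append(",".join(cells))
        return "\n".join(lines) + "\n"


def _child_seed(master: int, repeat: int, stream: int) -> int:
    ss = np.random.SeedSequence([master, repeat, stream])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _features_for(
    graph: CollabGraph, config: ExperimentConfig, seed: int
) -> FeatureMatrix:
    if config.feature_mode == "fused":
        provider = default_text_encoder(dim=config.embed_dim, seed=seed)
        return fuse_node_features(graph, provider, out_dim=config.feature_dim, seed=seed)
    if config.feature_mode == "structure":
        return structure_only_features(graph, out_dim=config.feature_dim, seed=seed)
    raise ValueError(f"unknown feature_mode {config.feature_mode!r}")


def _single_run(
    records: Sequence[TrialRecord], config: ExperimentConfig, repeat: int, master_seed: int
) -> dict:
    stage = "split"
    try:
        if config.split == "temporal":
            train_records = [
                r for r in records if r.year is not None and r.year <= config.cutoff_year
            ]
            graph = build_graph(train_records)
            split = temporal_split(records, graph, config.cutoff_year)
        elif config.split == "random":
            graph = build_graph(list(records))
            split = random_split_with_isolated(
                graph, config.test_fraction, rng_seed=_child_seed(master_seed, repeat, 0)
            )
        else:
            raise ValueError(f"unknown split strategy {config.split!r}")
        if not split.test_pos:
            raise SplitError("split produced no test positives")
        carve_validation(split, config.val_fraction, _child_seed(master_seed, repeat, 1))

        stage = "negatives"
        all_pos = set(split.train_pos) | set(split.val_pos) | set(split.test_pos)
        split.train_neg = sample_negatives(
            graph, split.train_pos, forbidden=all_pos,
            rng_seed=_child_seed(master_seed, repeat, 2),
        )
        taken = all_pos | set(split.train_neg)
        split.val_neg = sample_negatives(
            graph, split.val_pos, forbidden=taken,
            rng_seed=_child_seed(master_seed, repeat, 3),
        )
        taken |= set(split.val_neg)
        split.test_neg = sample_negatives(
            graph, split.test_pos, forbidden=taken,
            rng_seed=_child_seed(master_seed, repeat, 4),
        )
        split.validate()

        stage = "features"
        x = _features_for(graph, config, _child_seed(master_seed, repeat, 5))

        stage = "train"
        tcfg = TrainConfig(**{**asdict(config.train), "seed": _child_seed(master_seed, repeat, 6)})
        state, history = train(x, graph, split, config.model, tcfg)

        stage = "evaluate"
        order = graph.node_order
        a = training_adjacency(graph, split.train_pos)
        p = propagation_operator(a, config.model)
        h = encode(x.values, p, state, config.model)
        pos_scores = score_edges(h, _pairs_to_indices(split.test_pos, order))
        neg_scores = score_edges(h, _pairs_to_indices(split.test_neg, order))
        run_auc = auc(pos_scores, neg_scores)
        run_f1 = f1(
            np.concatenate([pos_scores, neg_scores]),
            np.concatenate([np.ones(len(pos_scores), dtype=int),
                            np.zeros(len(neg_scores), dtype=int)]),
        )

        # Accuracy@K over test users: candidates are the user's test-positive
        # partners plus sampled non-partners (pool size logged via config).
        index = {n: i for i, n in enumerate(order)}
        relevants: dict[str, set] = {}
        for u, v in split.test_pos:
            relevants.setdefault(u, set()).add(v)
            relevants.setdefault(v, set()).add(u)
        rng = np.random.default_rng(_child_seed(master_seed, repeat, 7))
        rankings: dict[str, list[str]] = {}
        for user in sorted(relevants):
            partners = graph.neighbors(user) | relevants[user] | {user}
            non_partners = [n for n in order if n not in partners]
            n_sample = min(config.candidate_pool, len(non_partners))
            sampled = [
                non_partners[i]
                for i in rng.choice(len(non_partners), size=n_sample, replace=False)
            ] if n_sample else []
            candidates = sorted(relevants[user]) + sampled
            scores = {
                c: float(h[index[user]] @ h[index[c]]) for c in candidates
            }
            rankings[user] = sorted(candidates, key=lambda c: (-scores[c], c))
        ks = range(1, config.k_max + 1)
        acc_by_mode = {
            mode: {k: accuracy_at_k(rankings, relevants, k, mode=mode) for k in ks}
            for mode in ("literal", "normalized")
        }
        return {
            "auc": run_auc,
            "f1": run_f1,
            "acc_at_k": acc_by_mode[config.acc_mode],
            "acc_at_k_literal": acc_by_mode["literal"],
            "n_train_pos": len(split.train_pos),
            "n_test_pos": len(split.test_pos),
            "n_test_users": len(relevants),
            "epochs_run": len(history),
        }
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc


def run_experiment(
    records: Sequence[TrialRecord],
    config: ExperimentConfig | None = None,
    master_seed: int | None = None,
) -> MetricsReport:
    """Run the full pipeline for ``n_repeats`` independent seeds.

    Each repeat re-draws the split randomness (random strategy), the
    negative samples, the weight initialization and the evaluation
    candidate pools from seeds derived deterministically from the master
    seed, then reports per-repeat AUC / F1 / Accuracy@K with mean and
    standard deviation.
    """
    config = config or ExperimentConfig()
    master = config.train.seed if master_seed is None else master_seed
    rows = [
        _single_run(records, config, repeat, master)
        for repeat in range(config.train.n_repeats)
    ]
    return MetricsReport.from_repeats(rows, acc_mode=config.acc_mode)
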