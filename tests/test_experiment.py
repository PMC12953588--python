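"""Edge splits, negative sampling, training loop and metrics."""

import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from trialgraph import (
    EdgeSplit,
    ModelConfig,
    TrainConfig,
    accuracy_at_k,
    auc,
    build_graph,
    f1,
    random_split_with_isolated,
    run_experiment,
    sample_negatives,
    temporal_split,
    train,
)
from trialgraph.exceptions import SamplingError, SplitError
from trialgraph.experiment import (
    ExperimentConfig,
    carve_validation,
    training_adjacency,
)
from trialgraph.features import FeatureMatrix

from conftest import make_record


class TestTemporalSplit:
    def test_pair_only_after_cutoff_is_test_positive(self):
        records = [
            make_record("NCT1", ["A", "B"], year=2020),
            make_record("NCT2", ["B", "C"], year=2021),
            make_record("NCT3", ["A", "C"], year=2022),
            make_record("NCT4", ["A", "D"], year=2022),
        ]
        graph = build_graph([r for r in records if r.year <= 2021])
        split = temporal_split(records, graph, 2021)
        # A-C first co-occur in 2022 and both are in the training graph;
        # A-D is new in 2022 but D never collaborated before the cutoff.
        assert split.test_pos == [("A", "C")]
        assert sorted(split.train_pos) == [("A", "B"), ("B", "C")]

    def test_pair_supported_before_and_after_is_train_only(self):
        records = [
            make_record("NCT1", ["A", "B"], year=2019),
            make_record("NCT2", ["A", "B"], year=2022),
        ]
        graph = build_graph(records[:1])
        split = temporal_split(records, graph, 2021)
        assert split.train_pos == [("A", "B")] and split.test_pos == []

    def test_counting_over_years(self):
        records = [
            make_record("NCT1", ["A", "B"], year=2015),
            make_record("NCT2", ["C", "D"], year=2021),
            make_record("NCT3", ["A", "C"], year=2022),
            make_record("NCT4", ["B", "D"], year=2022),
        ]
        graph = build_graph(records[:2])
        split = temporal_split(records, graph, 2021)
        assert len(split.train_pos) == 2 and len(split.test_pos) == 2

    def test_undated_records_rejected(self):
        records = [make_record("NCT1", ["A", "B"])]
        with pytest.raises(SplitError, match="random split"):
            temporal_split(records, build_graph(records), 2021)


class TestRandomSplit:
    def test_triangle_one_test_edge(self):
        g = build_graph([make_record("NCT1", ["A", "B", "C"])])
        split = random_split_with_isolated(g, 1 / 3, rng_seed=0)
        assert len(split.test_pos) == 1 and len(split.train_pos) == 2
        deg = {}
        for u, v in split.train_pos:
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
        assert set(deg) == {"A", "B", "C"}

    def test_star_leaf_edges_forced_to_train(self):
        g = build_graph([
            make_record("NCT1", ["Hub", "LeafA"]),
            make_record("NCT2", ["Hub", "LeafB"]),
        ])
        split = random_split_with_isolated(g, 0.5, rng_seed=1)
        assert len(split.test_pos) <= 1
        covered = {n for e in split.train_pos for n in e}
        assert covered == {"Hub", "LeafA", "LeafB"}

    def test_deterministic_per_seed(self, synth_small):
        records, _, _ = synth_small
        g = build_graph(records)
        s1 = random_split_with_isolated(g, 0.2, rng_seed=5)
        s2 = random_split_with_isolated(g, 0.2, rng_seed=5)
        assert s1.train_pos == s2.train_pos and s1.test_pos == s2.test_pos

    def test_every_node_keeps_a_train_edge(self, synth_small):
        records, _, _ = synth_small
        g = build_graph(records)
        split = random_split_with_isolated(g, 0.2, rng_seed=3)
        covered = {n for e in split.train_pos for n in e}
        nodes_with_edges = {n for e in g.edges for n in e}
        assert covered == nodes_with_edges


class TestSampleNegatives:
    def test_complete_graph_errors(self):
        g = build_graph([make_record("NCT1", ["A", "B", "C", "D"])])
        with pytest.raises(SamplingError, match="deficit"):
            sample_negatives(g, [("A", "B")] * 1, rng_seed=0)

    def test_path_graph_exhaustive_pool(self):
        g = build_graph([
            make_record("NCT1", ["A", "B"]),
            make_record("NCT2", ["B", "C"]),
            make_record("NCT3", ["C", "D"]),
        ])
        negs = sample_negatives(g, [("x", "y")] * 3, rng_seed=0)
        assert sorted(negs) == [("A", "C"), ("A", "D"), ("B", "D")]

    def test_zero_needed_empty(self, toy_graph):
        assert sample_negatives(toy_graph, [], rng_seed=0) == []

    def test_respects_forbidden_and_seed(self, synth_small):
        records, _, _ = synth_small
        g = build_graph(records)
        pos = sorted(g.edges)[:50]
        n1 = sample_negatives(g, pos, forbidden=set(), rng_seed=9)
        n2 = sample_negatives(g, pos, forbidden=set(n1), rng_seed=9)
        assert n1 == sample_negatives(g, pos, forbidden=set(), rng_seed=9)
        assert not set(n1) & set(n2)
        assert all(p not in g.edges for p in n1 + n2)


def two_clique_fixture():
    """Two 4-cliques with one-hot block features; linearly separable."""
    records = []
    blocks = [["A1", "A2", "A3", "A4"], ["B1", "B2", "B3", "B4"]]
    t = 0
    for block in blocks:
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                records.append(make_record(f"NCT{t}", [block[i], block[j]]))
                t += 1
    graph = build_graph(records)
    order = graph.node_order
    x = np.array([[1.0, 0.0] if n.startswith("A") else [0.0, 1.0] for n in order])
    return graph, FeatureMatrix(values=x, node_order=order)


def split_for(graph, seed=0):
    split = random_split_with_isolated(graph, 0.25, rng_seed=seed)
    split.train_neg = sample_negatives(
        graph, split.train_pos,
        forbidden=set(split.train_pos) | set(split.test_pos), rng_seed=seed,
    )
    return split


class TestTrain:
    def test_loss_decreases(self):
        graph, x = two_clique_fixture()
        split = split_for(graph)
        _, history = train(x, graph, split, ModelConfig(hidden_dim=8),
                           TrainConfig(max_epochs=50, patience=50, seed=0))
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_deterministic_history(self):
        graph, x = two_clique_fixture()
        split = split_for(graph)
        cfg = TrainConfig(max_epochs=20, patience=20, seed=4)
        _, h1 = train(x, graph, split, ModelConfig(hidden_dim=8), cfg)
        _, h2 = train(x, graph, split, ModelConfig(hidden_dim=8), cfg)
        assert h1 == h2

    def test_separable_toy_reaches_perfect_training_auc(self):
        from trialgraph.experiment import _pairs_to_indices
        from trialgraph.gnn_core import encode, propagation_operator, score_edges

        graph, x = two_clique_fixture()
        split = split_for(graph)
        mcfg = ModelConfig(hidden_dim=8)
        state, _ = train(x, graph, split, mcfg,
                         TrainConfig(max_epochs=100, patience=100, seed=1))
        p = propagation_operator(training_adjacency(graph, split.train_pos), mcfg)
        h = encode(x.values, p, state, mcfg)
        order = graph.node_order
        pos = score_edges(h, _pairs_to_indices(split.train_pos, order))
        neg = score_edges(h, _pairs_to_indices(split.train_neg, order))
        assert auc(pos, neg) >= 0.99

    def test_early_stopping_keeps_best_state(self):
        from trialgraph.experiment import _pairs_to_indices, _bce_with_logits
        from trialgraph.gnn_core import encode, propagation_operator

        graph, x = two_clique_fixture()
        split = split_for(graph, seed=2)
        carve_validation(split, 0.2, 3)
        split.val_neg = sample_negatives(
            graph, split.val_pos,
            forbidden=set(split.train_pos) | set(split.val_pos)
            | set(split.test_pos) | set(split.train_neg),
            rng_seed=7,
        )
        mcfg = ModelConfig(hidden_dim=8)
        state, history = train(x, graph, split, mcfg,
                               TrainConfig(max_epochs=60, patience=5, seed=5))
        p = propagation_operator(training_adjacency(graph, split.train_pos), mcfg)
        h = encode(x.values, p, state, mcfg)
        order = graph.node_order
        idx = np.vstack([_pairs_to_indices(split.val_pos, order),
                         _pairs_to_indices(split.val_neg, order)])
        labels = np.concatenate([np.ones(len(split.val_pos)), np.zeros(len(split.val_neg))])
        scores = np.einsum("ij,ij->i", h[idx[:, 0]], h[idx[:, 1]])
        returned_loss, _ = _bce_with_logits(scores, labels)
        assert returned_loss <= min(hh["val_loss"] for hh in history) + 1e-9


def brute_force_auc(pos, neg):
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([3, 4], [1, 2]) == 1.0

    def test_all_ties_half(self):
        assert auc([1.0, 1.0], [1.0, 1.0, 1.0]) == 0.5

    def test_hand_enumeration(self):
        assert auc([3, 1], [2, 0]) == 0.75

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auc([], [1.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 6, size=rng.integers(2, 20)).astype(float)
        neg = rng.integers(0, 6, size=rng.integers(2, 20)).astype(float)
        ours = auc(pos, neg)
        assert ours == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)
        labels = np.r_[np.ones(pos.size), np.zeros(neg.size)]
        assert ours == pytest.approx(roc_auc_score(labels, np.r_[pos, neg]))


def logit(p):
    return math.log(p / (1 - p))


class TestF1:
    def test_perfect_separation(self):
        scores = [logit(0.9), logit(0.8), logit(0.1)]
        assert f1(scores, [1, 1, 0]) == 1.0

    def test_no_predicted_positives_zero(self):
        assert f1([logit(0.2), logit(0.3)], [1, 0]) == 0.0

    def test_half_precision_half_recall(self):
        # TP=1, FP=1, FN=1 -> P = R = 0.5 -> F1 = 0.5
        scores = [logit(0.9), logit(0.8), logit(0.1)]
        assert f1(scores, [1, 0, 1]) == pytest.approx(0.5)

    def test_threshold_flag(self):
        scores = [logit(0.6), logit(0.4)]
        assert f1(scores, [1, 1], threshold=0.3) == 1.0


class TestAccuracyAtK:
    def test_single_user_hit(self):
        for mode in ("literal", "normalized"):
            assert accuracy_at_k({"u": ["a", "b"]}, {"u": {"a"}}, 1, mode) == 1.0

    def test_disjoint_topk_zero(self):
        assert accuracy_at_k({"u": ["b", "c"]}, {"u": {"a"}}, 2) == 0.0

    def test_two_user_normalized_average(self):
        rankings = {"u1": ["a", "b", "x"], "u2": ["x", "y"]}
        relevants = {"u1": {"a", "b", "c"}, "u2": {"z"}}
        assert accuracy_at_k(rankings, relevants, 2, "normalized") == pytest.approx(0.5)

    def test_literal_counts_hits(self):
        rankings = {"u1": ["a", "b", "x"]}
        relevants = {"u1": {"a", "b", "c"}}
        assert accuracy_at_k(rankings, relevants, 2, "literal") == 2.0

    def test_literal_k_inf_conserves_mean_relevants(self):
        rankings = {"u1": ["a", "b", "c", "d"], "u2": ["c", "d", "a"]}
        relevants = {"u1": {"a", "b"}, "u2": {"c", "d", "a"}}
        expected = (2 + 3) / 2
        assert accuracy_at_k(rankings, relevants, math.inf, "literal") == expected

    def test_empty_relevants_skipped(self, caplog):
        rankings = {"u1": ["a"], "u2": ["b"]}
        relevants = {"u1": {"a"}, "u2": set()}
        assert accuracy_at_k(rankings, relevants, 1) == 1.0


@pytest.fixture(scope="module")
def small_config():
    return ExperimentConfig(
        feature_dim=32, embed_dim=8, candidate_pool=20,
        model=ModelConfig(hidden_dim=32),
        train=TrainConfig(max_epochs=30, n_repeats=2),
    )


@pytest.fixture(scope="module")
def report(synth_small, small_config):
    records, _, _ = synth_small
    return run_experiment(records, small_config, master_seed=11)


class TestRunExperiment:
    def test_deterministic_report(self, synth_small, small_config, report):
        records, _, _ = synth_small
        again = run_experiment(records, small_config, master_seed=11)
        assert again.to_json() == report.to_json()

    def test_literal_acc_at_k_monotone(self, report):
        """Top-k lists are nested, so literal hit counts cannot decrease."""
        for row in report.per_repeat:
            ks = sorted(row["acc_at_k_literal"])
            vals = [row["acc_at_k_literal"][k] for k in ks]
            assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_metrics_in_range(self, report):
        assert 0 <= report.auc_mean <= 1
        assert 0 <= report.f1_mean <= 1
        assert report.n_repeats == 2

    def test_stage_tagged_errors(self, synth_small, small_config):
        records, _, _ = synth_small
        bad = ExperimentConfig(
            split="temporal", cutoff_year=1990,
            train=small_config.train, model=small_config.model,
        )
        with pytest.raises(SplitError, match="stage"):
            run_experiment(records, bad, master_seed=0)


class TestSplitInvariants:
    @pytest.mark.parametrize("strategy", ["temporal", "random"])
    @pytest.mark.parametrize("seed", range(5))
    def test_full_split_satisfies_all_invariants(self, synth_small, strategy, seed):
        records, _, _ = synth_small
        if strategy == "temporal":
            graph = build_graph([r for r in records if r.year <= 2021])
            split = temporal_split(records, graph, 2021)
        else:
            graph = build_graph(records)
            split = random_split_with_isolated(graph, 0.2, rng_seed=seed)
        carve_validation(split, 0.1, seed)
        all_pos = set(split.train_pos) | set(split.val_pos) | set(split.test_pos)
        split.train_neg = sample_negatives(graph, split.train_pos, all_pos, seed + 1)
        taken = all_pos | set(split.train_neg)
        split.val_neg = sample_negatives(graph, split.val_pos, taken, seed + 2)
        taken |= set(split.val_neg)
        split.test_neg = sample_negatives(graph, split.test_pos, taken, seed + 3)
        split.validate()  # raises on any violation
        assert len(split.train_neg) == len(split.train_pos)
        assert len(split.test_neg) == len(split.test_pos)

    def test_validate_catches_overlap(self):
        split = EdgeSplit(train_pos=[("A", "B")], test_pos=[("A", "B")])
        with pytest.raises(SplitError):
            split.validate(require_negatives=False)

    def test_validate_catches_ratio(self):
        split = EdgeSplit(train_pos=[("A", "B")], train_neg=[])
        with pytest.raises(SplitError, match="1:1"):
            split.validate()


class TestLeakage:
    def test_features_ignore_test_year_records(self, synth_small):
        """Temporal features must derive only from train-period records."""
        from trialgraph import fuse_node_features

        records, _, _ = synth_small
        train_records = [r for r in records if r.year <= 2021]
        g_train = build_graph(train_records)
        # adding the 2022 records must not change train-built features
        f_before = fuse_node_features(g_train, out_dim=16, seed=0)
        g_again = build_graph(train_records)
        f_after = fuse_node_features(g_again, out_dim=16, seed=0)
        assert np.array_equal(f_before.values, f_after.values)
        # and the training adjacency carries no test positives
        split = temporal_split(records, g_train, 2021)
        a = training_adjacency(g_train, split.train_pos)
        order = g_train.node_order
        index = {n: i for i, n in enumerate(order)}
        for u, v in split.test_pos:
            assert a[index[u], index[v]] == 0
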