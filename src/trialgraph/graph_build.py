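"""Construction of the cumulative weighted co-collaboration graph.

Every trial contributes a clique over its affiliations: each unordered pair
gains one unit of edge weight (collaboration count) and each affiliation one
unit of node weight (trial count).  The graph is undirected and cumulative —
repeated collaborations stack — and carries per-node attribute tallies
(countries, intervention categories) plus a per-edge normalized intervention
attribute used later for feature fusion and weighted message passing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .registry_io import TrialRecord, filter_by_condition

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def edge_key(u: str, v: str) -> Pair:
    """Canonical unordered edge key (sorted endpoint pair)."""
    return (u, v) if u <= v else (v, u)


@dataclass
class NodeInfo:
    trial_count: int = 0
    country_counts: dict[str, int] = field(default_factory=dict)
    intervention_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class EdgeInfo:
    collab_count: int = 0
    intervention_raw: int = 0          # co-trials carrying >=1 intervention
    intervention_norm: float = 0.0     # min-max scaled across edges


@dataclass
class CollabGraph:
    """Undirected cumulative weighted collaboration graph.

    ``node_order`` (lexicographic by canonical name) fixes the row order of
    every matrix derived from the graph, so results are reproducible across
    runs and record orderings.
    """

    nodes: dict[str, NodeInfo] = field(default_factory=dict)
    edges: dict[Pair, EdgeInfo] = field(default_factory=dict)

    @property
    def node_order(self) -> list[str]:
        return sorted(self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, name: str) -> set[str]:
        out = set()
        for (u, v) in self.edges:
            if u == name:
                out.add(v)
            elif v == name:
                out.add(u)
        return out

    def categories(self) -> list[str]:
        """Sorted union of intervention categories seen on any node."""
        cats: set[str] = set()
        for info in self.nodes.values():
            cats.update(info.intervention_counts)
        return sorted(cats)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for name, info in self.nodes.items():
            g.add_node(name, trial_count=info.trial_count)
        for (u, v), e in self.edges.items():
            g.add_edge(u, v, collab_count=e.collab_count,
                       intervention_norm=e.intervention_norm)
        return g

    def write_tables(self, node_path: str | Path, edge_path: str | Path) -> None:
        """Serialize as node / edge TSV tables for inspection."""
        with open(node_path, "w", encoding="utf-8") as fh:
            fh.write("name\ttrial_count\ttop_country\tintervention_counts\n")
            for name in self.node_order:
                info = self.nodes[name]
                top = dominant(info.country_counts)
                fh.write(
                    f"{name}\t{info.trial_count}\t{top}\t"
                    f"{json.dumps(info.intervention_counts, sort_keys=True)}\n"
                )
        with open(edge_path, "w", encoding="utf-8") as fh:
            fh.write("u\tv\tcollab_count\tintervention_norm\n")
            for (u, v) in sorted(self.edges):
                e = self.edges[(u, v)]
                fh.write(f"{u}\t{v}\t{e.collab_count}\t{e.intervention_norm:.6g}\n")


def dominant(counts: dict[str, int]) -> str:
    """Mode of a count table; ties broken lexicographically; '' if empty."""
    if not counts:
        return ""
    return min(counts, key=lambda k: (-counts[k], k))


def build_graph(records: Sequence[TrialRecord]) -> CollabGraph:
    """Accumulate the collaboration graph over trial records.

    Per trial: every unordered affiliation pair gains +1 collaboration
    count, every affiliation +1 trial count, and node country/intervention
    tallies grow.  Single-affiliation trials yield isolated nodes.  A trial
    listing the same affiliation twice (post-canonicalization) counts once
    and creates no self-loop.
    """
    g = CollabGraph()
    for r in records:
        affils = list(dict.fromkeys(r.affiliations))
        has_intervention = len(r.interventions) > 0
        for a in affils:
            info = g.nodes.setdefault(a, NodeInfo())
            info.trial_count += 1
            for c in r.countries:
                info.country_counts[c] = info.country_counts.get(c, 0) + 1
            for cat, _name in r.interventions:
                info.intervention_counts[cat] = info.intervention_counts.get(cat, 0) + 1
        for a, b in combinations(affils, 2):
            e = g.edges.setdefault(edge_key(a, b), EdgeInfo())
            e.collab_count += 1
            if has_intervention:
                e.intervention_raw += 1
    return normalize_edge_interventions(g)


def condition_subgraph(
    records: Sequence[TrialRecord], keywords: Sequence[str]
) -> CollabGraph:
    """Disease-centric subgraph: build only from trials matching keywords."""
    return build_graph(filter_by_condition(records, keywords))


def normalize_edge_interventions(graph: CollabGraph) -> CollabGraph:
    """Min-max scale the raw per-edge intervention counts into [0, 1].

    When all raw counts coincide (including the single-edge case) every
    edge gets 1.0 so a uniform attribute does not zero out edge information.
    Edgeless graphs are a warned no-op.
    """
    if not graph.edges:
        logger.warning("normalize_edge_interventions: graph has no edges")
        return graph
    raws = [e.intervention_raw for e in graph.edges.values()]
    lo, hi = min(raws), max(raws)
    for e in graph.edges.values():
        e.intervention_norm = 1.0 if hi == lo else (e.intervention_raw - lo) / (hi - lo)
    return graph


def adjacency(
    graph: CollabGraph, weighted: bool = True, scale_by_intervention: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Symmetric adjacency matrix in the stable node order.

    Entries are collaboration counts when ``weighted`` (optionally scaled by
    the edge's normalized intervention attribute), else 1/0.  Diagonal is
    zero.  Returns (matrix, node order).
    """
    order = graph.node_order
    index = {n: i for i, n in enumerate(order)}
    a = np.zeros((len(order), len(order)))
    for (u, v), e in graph.edges.items():
        w = float(e.collab_count) if weighted else 1.0
        if weighted and scale_by_intervention:
            w *= e.intervention_norm
        a[index[u], index[v]] = w
        a[index[v], index[u]] = w
    return a, order
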