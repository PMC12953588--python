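"""Ranked collaboration-partner recommendations for a target affiliation.

Given trained node embeddings, every other node is a candidate partner;
candidates are scored by the dot product with the target's embedding and
returned in descending score order.  Scores are reported both raw and
sigmoid-transformed, since the dot product acts as an unnormalized link
probability.
"""

from __future__ import annotations

import difflib
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .graph_build import CollabGraph


@dataclass(frozen=True)
class RankedCandidate:
    name: str
    score: float
    probability: float
    already_partner: bool


@dataclass
class Ranking:
    """Descending ranking of candidate partners for one target affiliation.

    Sorted by (score desc, name asc); the target itself is excluded.
    """

    target: str
    entries: list[RankedCandidate]

    def to_tsv(self) -> str:
        lines = ["rank\tcandidate\tscore\tprobability\texisting_partner"]
        for i, e in enumerate(self.entries, 1):
            lines.append(
                f"{i}\t{e.name}\t{e.score:.6g}\t{e.probability:.6g}\t"
                f"{'yes' if e.already_partner else 'no'}"
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "target": self.target,
                "entries": [
                    {
                        "rank": i + 1,
                        "candidate": e.name,
                        "score": e.score,
                        "probability": e.probability,
                        "existing_partner": e.already_partner,
                    }
                    for i, e in enumerate(self.entries)
                ],
            },
            indent=2,
        )


def recommend_top_n(
    graph: CollabGraph,
    h: np.ndarray,
    target: str,
    n: int = 10,
    include_existing: bool = True,
    node_order: Sequence[str] | None = None,
) -> Ranking:
    """Top-N partner recommendations for ``target``.

    With ``include_existing`` the candidate set is every other node
    (existing and potential partners alike); otherwise only non-partners
    are considered.  Ties are broken lexicographically by name so output
    is deterministic.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    order = list(node_order) if node_order is not None else graph.node_order
    if target not in graph.nodes:
        close = difflib.get_close_matches(target, order, n=3)
        hint = f"; closest names: {', '.join(close)}" if close else ""
        raise KeyError(f"unknown affiliation {target!r}{hint}")
    index = {name: i for i, name in enumerate(order)}
    partners = graph.neighbors(target)
    h_t = h[index[target]]
    entries = []
    for name in order:
        if name == target:
            continue
        is_partner = name in partners
        if not include_existing and is_partner:
            continue
        s = float(h_t @ h[index[name]])
        entries.append(
            RankedCandidate(
                name=name,
                score=s,
                probability=1.0 / (1.0 + math.exp(-s)),
                already_partner=is_partner,
            )
        )
    entries.sort(key=lambda e: (-e.score, e.name))
    return Ranking(target=target, entries=entries[:n])
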