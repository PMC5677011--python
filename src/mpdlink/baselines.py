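"""Local similarity indices used as comparators: CN, AA, RA.

All three score a node pair through its common neighbors on the binary
undirected view of the training graph (for a digraph,
Γ(x) = in-neighbors ∪ out-neighbors; weights are ignored):

* CN — common-neighbor count |Γ(x) ∩ Γ(y)|;
* AA — Σ_z 1/ln|Γ(z)| over common neighbors z (natural logarithm);
* RA — Σ_z 1/|Γ(z)|.

A common neighbor of two distinct nodes has degree ≥ 2, so neither
weighted sum can divide by zero or by ln 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .graph_core import WeightedDigraph

__all__ = ["NeighborSets", "cn_score", "aa_score", "ra_score", "score_all_pairs"]


@dataclass
class NeighborSets:
    """Neighbor sets Γ(x) and degrees on the undirected view."""

    neighbors: dict
    degree: dict

    @classmethod
    def from_graph(cls, g: WeightedDigraph) -> "NeighborSets":
        nbrs = {u: set() for u in g.nodes}
        for u, v in g.links:
            nbrs[u].add(v)
            nbrs[v].add(u)
        return cls(nbrs, {u: len(s) for u, s in nbrs.items()})

    def _common(self, x, y):
        if x == y:
            raise ValueError("similarity indices are defined for distinct nodes")
        try:
            return self.neighbors[x] & self.neighbors[y]
        except KeyError as exc:
            raise KeyError(f"unknown node {exc.args[0]!r}") from exc


def cn_score(ns: NeighborSets, x, y) -> int:
    """Common-neighbor count."""
    return len(ns._common(x, y))


def aa_score(ns: NeighborSets, x, y) -> float:
    """Adamic–Adar: common neighbors weighted by 1/ln(degree)."""
    return sum(1.0 / math.log(ns.degree[z]) for z in ns._common(x, y))


def ra_score(ns: NeighborSets, x, y) -> float:
    """Resource allocation: common neighbors weighted by 1/degree."""
    return sum(1.0 / ns.degree[z] for z in ns._common(x, y))


_SCORERS = {"CN": cn_score, "AA": aa_score, "RA": ra_score}


def score_all_pairs(ns: NeighborSets, pairs, index: str) -> dict:
    """Score every candidate pair with the named index."""
    try:
        fn = _SCORERS[index]
    except KeyError:
        raise ValueError(f"unknown index {index!r}; expected CN, AA or RA")
    return {pair: fn(ns, *pair) for pair in pairs}
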