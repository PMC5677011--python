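"""Fixture factory: planted matrices and stochastic-block-model graphs.

Everything downstream is testable without external downloads:

* :func:`planted_low_rank_sparse` builds an observed matrix L0 + S0 with a
  known low-rank part (product of two Gaussian factors) and known sparse
  corruption — the exact-recovery test bed for the robust-PCA stage;
* :func:`sbm_graph` draws a stochastic block model, whose planted community
  structure is the low-rank organisation the full pipeline should exploit;
* :func:`karate_club_graph` loads the frozen 34-node Zachary karate club
  edge list shipped with the package, the one real network whose printed
  descriptors serve as a worked example.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np

from .graph_core import WeightedDigraph, read_edge_list

__all__ = [
    "PlantedMatrixSpec",
    "SbmSpec",
    "planted_low_rank_sparse",
    "sbm_graph",
    "karate_club_graph",
]


@dataclass
class PlantedMatrixSpec:
    size: int
    rank: int
    corruption_fraction: float = 0.01
    corruption_magnitude: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.rank > self.size or self.rank < 0:
            raise ValueError("rank must be in [0, size]")
        if not 0.0 <= self.corruption_fraction < 1.0:
            raise ValueError("corruption_fraction must be in [0, 1)")
        if self.corruption_magnitude <= 0:
            raise ValueError("corruption_magnitude must be positive")


@dataclass
class SbmSpec:
    block_sizes: list
    p_within: float
    p_between: float
    directed: bool = False
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_within, self.p_between):
            if not 0.0 <= p <= 1.0:
                raise ValueError("link probabilities must lie in [0, 1]")


def planted_low_rank_sparse(spec: PlantedMatrixSpec):
    """Observed = L0 + S0 with L0 = X·Yᵀ (X, Y n×r standard normal) and S0
    holding ±corruption_magnitude at a uniform random fraction of entries
    (chosen without replacement).  Returns (observed, L0, S0)."""
    rng = np.random.default_rng(spec.seed)
    n, r = spec.size, spec.rank
    if r == 0:
        low_rank = np.zeros((n, n))
    else:
        low_rank = rng.standard_normal((n, r)) @ rng.standard_normal((n, r)).T
    sparse = np.zeros((n, n))
    n_corrupt = int(round(spec.corruption_fraction * n * n))
    if n_corrupt:
        flat = rng.choice(n * n, size=n_corrupt, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_corrupt)
        sparse.flat[flat] = signs * spec.corruption_magnitude
    return low_rank + sparse, low_rank, sparse


def sbm_graph(spec: SbmSpec) -> WeightedDigraph:
    """Stochastic block model with unit weights; independent link coin-flips
    with probability p_within inside a block and p_between across blocks."""
    probs = [
        [spec.p_within if i == j else spec.p_between for j in range(len(spec.block_sizes))]
        for i in range(len(spec.block_sizes))
    ]
    h = nx.stochastic_block_model(
        spec.block_sizes, probs, seed=spec.seed, directed=spec.directed, selfloops=False
    )
    links = {}
    for u, v in h.edges():
        links[(u, v)] = 1.0
        if not spec.directed:
            links[(v, u)] = 1.0
    return WeightedDigraph(sorted(h.nodes()), links, spec.directed)


def karate_club_graph() -> WeightedDigraph:
    """The canonical 34-node, 78-edge Zachary karate club network."""
    path = resources.files("mpdlink.data").joinpath("karate.tsv")
    with resources.as_file(path) as p:
        return read_edge_list(p, directed=False, weighted=False)
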