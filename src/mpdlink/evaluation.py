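"""Train/probe splitting, score ranking, precision@L and AUC.

The link set E is partitioned at random into a training set E^T (observed)
and a probe set E^P (the prediction target); every predictor sees only E^T
and assigns a likelihood score to each candidate pair absent from E^T.

precision@L ranks the candidates by score and reports the fraction of the
top L that lie in the probe set (the protocol takes L = |E^P|).  Ties are
broken by a seeded random shuffle to avoid insertion-order bias.

AUC is the probability that a random probe link outscores a random
nonexistent link, ties counted half: exact mode evaluates the full
Mann–Whitney statistic, sampled mode draws ``n`` independent probe/
nonexistent comparisons and returns (n' + 0.5 n'')/n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import floor

import numpy as np
import scipy.stats

from .graph_core import WeightedDigraph

logger = logging.getLogger("mpdlink")

__all__ = [
    "EdgeSplit",
    "ScoreTable",
    "EvalMetrics",
    "split_edges",
    "scores_from_matrix",
    "precision_at_L",
    "auc",
]

#: above this many probe x nonexistent comparisons, AUC falls back to sampling
EXACT_AUC_LIMIT = 10**8
SAMPLED_AUC_DRAWS = 672_400


def _round_half_away(x: float) -> int:
    return int(floor(x + 0.5)) if x >= 0 else -int(floor(-x + 0.5))


@dataclass
class EdgeSplit:
    """Disjoint exhaustive partition of the links into training and probe."""

    graph: WeightedDigraph
    training: set
    probe: set
    seed: int

    def __post_init__(self):
        if self.training & self.probe:
            raise ValueError("training and probe sets must be disjoint")
        if not self.probe:
            raise ValueError("probe set must be nonempty")
        units = set(self.graph.edge_units())
        if self.training | self.probe != units:
            raise ValueError("training ∪ probe must equal the full link set")

    def training_graph(self) -> WeightedDigraph:
        return self.graph.subgraph_with_links(self.training)


@dataclass
class ScoreTable:
    """Candidate pair → likelihood score; the common currency of predictors.

    Candidates are exactly the node pairs absent from the training link set
    (unordered for undirected evaluation, ordered for directed).
    """

    scores: dict
    directed: bool = True

    @property
    def candidates(self) -> set:
        return set(self.scores)


@dataclass
class EvalMetrics:
    precision: float
    auc: float
    L: int
    n_comparisons: object = "exact"  # int for sampled mode


def split_edges(g: WeightedDigraph, probe_fraction: float, seed: int) -> EdgeSplit:
    """Uniform random probe of size round(probe_fraction·|E|), min 1.

    For undirected graphs the sampling unit is the unordered pair.
    Reproducible per seed.
    """
    if not 0.0 < probe_fraction < 1.0:
        raise ValueError(f"probe_fraction must be in (0,1), got {probe_fraction}")
    units = g.edge_units()
    if len(units) < 2:
        raise ValueError("graph must have at least 2 links to split")
    k = max(1, _round_half_away(probe_fraction * len(units)))
    k = min(k, len(units) - 1)  # training must stay nonempty
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(units), size=k, replace=False)
    probe = {units[i] for i in pick}
    training = set(units) - probe
    return EdgeSplit(g, training, probe, seed)


def scores_from_matrix(backbone: np.ndarray, split: EdgeSplit, directed: bool) -> ScoreTable:
    """Read candidate scores off a score matrix (entry = target row, source col).

    Candidates are all non-training, non-self pairs.  For undirected
    evaluation the score of the unordered pair {i, j} is the mean of the
    (i, j) and (j, i) entries.
    """
    backbone = np.asarray(backbone, dtype=float)
    g = split.graph
    n = g.n_nodes
    if backbone.shape != (n, n):
        raise ValueError(
            f"score matrix shape {backbone.shape} does not match node count {n}"
        )
    index = {u: i for i, u in enumerate(g.nodes)}
    scores = {}
    if directed:
        for u in g.nodes:
            for v in g.nodes:
                if u != v and (u, v) not in split.training:
                    scores[(u, v)] = float(backbone[index[v], index[u]])
    else:
        for a in range(n):
            for b in range(a + 1, n):
                u, v = g.nodes[a], g.nodes[b]
                if (u, v) not in split.training:
                    scores[(u, v)] = float(
                        (backbone[index[v], index[u]] + backbone[index[u], index[v]]) / 2.0
                    )
    if not scores:
        logger.warning("no unobserved pairs: the training graph is complete")
    return ScoreTable(scores, directed)


def _canonical_probe(st: ScoreTable, split_or_probe) -> set:
    probe = split_or_probe.probe if isinstance(split_or_probe, EdgeSplit) else set(split_or_probe)
    missing = {p for p in probe if tuple(p) not in st.scores and tuple(p)[::-1] not in st.scores}
    if missing:
        raise ValueError(
            f"probe links absent from candidate set (split/score mismatch): {sorted(missing)[:5]}"
        )
    return {p if tuple(p) in st.scores else tuple(p)[::-1] for p in map(tuple, probe)}


def precision_at_L(st: ScoreTable, probe, L: int, seed: int = 0) -> float:
    """Fraction of the top-L ranked candidates that lie in the probe set."""
    probe = _canonical_probe(st, probe)
    if L < 1 or L > len(st.scores):
        raise ValueError(f"L must be in [1, {len(st.scores)}], got {L}")
    pairs = list(st.scores)
    values = np.array([st.scores[p] for p in pairs])
    rng = np.random.default_rng(seed)
    shuffle = rng.permutation(len(pairs))  # tie-break: seeded random order
    order = np.lexsort((shuffle, -values))
    hits = sum(1 for i in order[:L] if pairs[i] in probe)
    return hits / L


def auc(st: ScoreTable, probe, n_comparisons="exact", seed: int = 0):
    """AUC = P(random probe link outscores random nonexistent link).

    ``n_comparisons="exact"`` computes the full Mann–Whitney statistic with
    half-credit ties (falling back to sampling above ``EXACT_AUC_LIMIT``
    pairwise comparisons); an integer requests that many sampled
    comparisons.  Returns ``(auc_value, n_comparisons_used)``.
    """
    probe = _canonical_probe(st, probe)
    probe_scores = np.array([st.scores[p] for p in probe])
    nonexistent_scores = np.array(
        [s for p, s in st.scores.items() if p not in probe]
    )
    if len(nonexistent_scores) == 0:
        raise ValueError("no nonexistent candidate links to compare against")
    n_pairs = len(probe_scores) * len(nonexistent_scores)
    if n_comparisons == "exact" and n_pairs > EXACT_AUC_LIMIT:
        n_comparisons = SAMPLED_AUC_DRAWS
    if n_comparisons == "exact":
        # Mann-Whitney U via midranks: U/(n1*n2) is exactly (n' + 0.5 n'')/n
        ranks = scipy.stats.rankdata(
            np.concatenate([probe_scores, nonexistent_scores])
        )
        n1 = len(probe_scores)
        u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
        return u / n_pairs, "exact"
    n = int(n_comparisons)
    if n < 1:
        raise ValueError("n_comparisons must be positive or 'exact'")
    rng = np.random.default_rng(seed)
    a = probe_scores[rng.integers(0, len(probe_scores), size=n)]
    b = nonexistent_scores[rng.integers(0, len(nonexistent_scores), size=n)]
    return float(((a > b).sum() + 0.5 * (a == b).sum()) / n), n
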