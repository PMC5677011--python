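"""Topological descriptors of a network.

All descriptors are computed on the binary undirected view of the input:
mean local clustering coefficient C, degree assortativity r (Pearson
correlation of end-point degrees over edges), mean degree <k> = 2|E|/|V|,
mean shortest-path length <d> over connected ordered pairs, and degree
heterogeneity H = <k^2>/<k>^2 (1 for regular graphs, larger for broader
degree distributions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_core import WeightedDigraph

logger = logging.getLogger("mpdlink")

__all__ = ["NetworkStats", "compute_stats"]


@dataclass
class NetworkStats:
    n_nodes: int
    n_links: int
    clustering: float
    assortativity: float
    mean_degree: float
    mean_distance: float
    heterogeneity: float

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_links": self.n_links,
            "clustering": self.clustering,
            "assortativity": self.assortativity,
            "mean_degree": self.mean_degree,
            "mean_distance": self.mean_distance,
            "heterogeneity": self.heterogeneity,
        }


def _undirected_view(g: WeightedDigraph) -> nx.Graph:
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    h.add_edges_from((u, v) for u, v in g.links)
    return h


def compute_stats(g: WeightedDigraph) -> NetworkStats:
    """Descriptor row for one network (binary undirected view)."""
    if g.n_nodes == 0:
        raise ValueError("cannot compute descriptors of an empty graph")
    h = _undirected_view(g)
    deg = np.array([d for _, d in h.degree()], dtype=float)
    k1 = deg.mean()
    het = float((deg**2).mean() / k1**2) if k1 > 0 else float("nan")
    if h.number_of_edges() > 0 and not nx.is_connected(h):
        logger.warning(
            "graph is disconnected; mean distance computed on the largest component"
        )
        comp = h.subgraph(max(nx.connected_components(h), key=len))
    else:
        comp = h
    mean_d = (
        float(nx.average_shortest_path_length(comp))
        if comp.number_of_nodes() > 1
        else float("nan")
    )
    try:
        with np.errstate(invalid="ignore"):  # regular graphs: 0/0 -> nan
            r = float(nx.degree_assortativity_coefficient(h))
    except (ZeroDivisionError, ValueError):
        r = float("nan")
    return NetworkStats(
        n_nodes=h.number_of_nodes(),
        n_links=h.number_of_edges(),
        clustering=float(nx.average_clustering(h)),
        assortativity=r,
        mean_degree=float(k1),
        mean_distance=mean_d,
        heterogeneity=het,
    )
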