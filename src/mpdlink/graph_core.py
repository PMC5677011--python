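"""Graph and matrix data model plus readers/writers.

The toolkit operates on weighted directed (or undirected) networks
``G(V, E, A)``.  The adjacency convention follows the usual source-column /
target-row form: entry ``A[i, j] > 0`` iff the link ``(v_j -> v_i)`` exists,
with the weight as the entry value.  The whole perturbation/decomposition
algebra is invariant under transposition, so one convention is kept
everywhere and documented here.

Supported external formats:

* edge list — whitespace/TAB separated, 2 or 3 columns, ``#`` comments;
* dense adjacency — CSV, optional header row of node names;
* sparse adjacency — Matrix Market coordinate format.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import scipy.io
import scipy.sparse

logger = logging.getLogger("mpdlink")

__all__ = [
    "WeightedDigraph",
    "AdjacencyMatrix",
    "read_edge_list",
    "write_edge_list",
    "to_adjacency",
    "from_adjacency",
    "read_dense_csv",
    "write_dense_csv",
    "read_matrix_market",
    "write_matrix_market",
]

#: tolerance used when an allegedly symmetric matrix is checked
SYMMETRY_TOL = 1e-12


class GraphFormatError(ValueError):
    """Malformed input file (bad line, bad weight, wrong shape)."""


@dataclass
class WeightedDigraph:
    """A node set plus ordered weighted links; the universal input object.

    ``links`` maps the ordered pair ``(u, v)`` — a link from ``u`` to ``v`` —
    to a strictly positive weight.  For undirected graphs both orientations
    are stored with equal weight, so the map is symmetric by construction.
    """

    nodes: list
    links: dict
    directed: bool = True

    def __post_init__(self):
        index = {u: i for i, u in enumerate(self.nodes)}
        if len(index) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        for (u, v), w in self.links.items():
            if u == v:
                raise ValueError(f"self-loop ({u},{u}) not allowed")
            if u not in index or v not in index:
                raise ValueError(f"link ({u},{v}) references unknown node")
            if not w > 0:
                raise ValueError(f"nonpositive weight {w} on link ({u},{v})")
        if not self.directed:
            for (u, v), w in self.links.items():
                if self.links.get((v, u)) != w:
                    raise ValueError(
                        f"undirected graph must store ({v},{u}) with weight {w}"
                    )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        """Number of links: ordered pairs if directed, unordered otherwise."""
        n = len(self.links)
        return n if self.directed else n // 2

    def edge_units(self) -> list:
        """Canonical link units: ordered pairs for directed graphs, each
        unordered pair once (lexicographic by node position) otherwise."""
        if self.directed:
            return sorted(self.links, key=self._pair_key)
        pos = {u: i for i, u in enumerate(self.nodes)}
        units = {tuple(sorted(p, key=pos.__getitem__)) for p in self.links}
        return sorted(units, key=self._pair_key)

    def _pair_key(self, pair):
        pos = {u: i for i, u in enumerate(self.nodes)}
        return (pos[pair[0]], pos[pair[1]])

    def subgraph_with_links(self, keep: Iterable[tuple]) -> "WeightedDigraph":
        """Same node set, links restricted to ``keep`` (canonical units)."""
        links = {}
        for u, v in keep:
            links[(u, v)] = self.links[(u, v)]
            if not self.directed:
                links[(v, u)] = self.links[(v, u)]
        return WeightedDigraph(list(self.nodes), links, self.directed)


@dataclass
class AdjacencyMatrix:
    """Dense weighted adjacency with its node ordering.

    ``values[i, j]`` is the weight of the link ``(nodes[j] -> nodes[i])``.
    """

    values: np.ndarray
    nodes: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("adjacency matrix must be square")
        n = self.values.shape[0]
        if not self.nodes:
            self.nodes = list(range(n))
        if len(self.nodes) != n:
            raise ValueError("node list length must match matrix dimension")
        if np.any(self.values < 0):
            raise ValueError("adjacency entries must be nonnegative")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("adjacency diagonal must be zero (no self-loops)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def node_index(self) -> dict:
        return {u: i for i, u in enumerate(self.nodes)}


# ---------------------------------------------------------------------------
# conversions

def to_adjacency(g: WeightedDigraph) -> AdjacencyMatrix:
    """Adjacency of ``g``: entry (i, j) = weight of link (nodes[j] -> nodes[i])."""
    if g.n_nodes == 0:
        raise ValueError("cannot build adjacency of an empty graph")
    n = g.n_nodes
    index = {u: i for i, u in enumerate(g.nodes)}
    m = np.zeros((n, n))
    for (u, v), w in g.links.items():
        m[index[v], index[u]] = w
    return AdjacencyMatrix(m, list(g.nodes))


def from_adjacency(m: AdjacencyMatrix, directed: bool = True) -> WeightedDigraph:
    """Inverse of :func:`to_adjacency` under the same convention."""
    if not directed:
        asym = np.max(np.abs(m.values - m.values.T)) if m.n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(
                f"asymmetric matrix (max |A - A^T| = {asym:g}) with directed=False"
            )
    links = {}
    rows, cols = np.nonzero(m.values)
    for i, j in zip(rows, cols):
        links[(m.nodes[j], m.nodes[i])] = float(m.values[i, j])
    return WeightedDigraph(list(m.nodes), links, directed)


# ---------------------------------------------------------------------------
# edge lists

def read_edge_list(
    path, directed: bool = True, weighted: bool = True
) -> WeightedDigraph:
    """Read a whitespace/TAB-separated edge list.

    Lines hold ``source target [weight]``; ``#`` starts a comment.  For
    undirected input each line installs both orientations.  Duplicate lines
    collapse to the last weight seen; unweighted lines get weight 1.
    Self-loop lines are skipped with a warning.
    """
    nodes: list = []
    seen: set = set()
    links: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) not in (2, 3):
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 2 or 3 fields, got {len(fields)}"
                )
            u, v = fields[0], fields[1]
            if len(fields) == 3 and weighted:
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise GraphFormatError(
                        f"{path}:{lineno}: bad weight {fields[2]!r}"
                    ) from exc
            else:
                w = 1.0
            if not w > 0:
                raise GraphFormatError(
                    f"{path}:{lineno}: nonpositive weight {w}"
                )
            if u == v:
                logger.warning("%s:%d: skipping self-loop on %r", path, lineno, u)
                continue
            for node in (u, v):
                if node not in seen:
                    seen.add(node)
                    nodes.append(node)
            links[(u, v)] = w
            if not directed:
                links[(v, u)] = w
    return WeightedDigraph(nodes, links, directed)


def write_edge_list(g: WeightedDigraph, path) -> None:
    """Write canonical link units, TAB separated, weights always included."""
    with open(path, "w") as fh:
        for u, v in g.edge_units():
            fh.write(f"{u}\t{v}\t{g.links[(u, v)]:.17g}\n")


# ---------------------------------------------------------------------------
# dense CSV and Matrix Market adjacency

def read_dense_csv(path, header: bool | None = None) -> AdjacencyMatrix:
    """Dense adjacency from CSV; autodetects a header row of node names."""
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if row]
    if not rows:
        raise GraphFormatError(f"{path}: empty file")
    if header is None:
        try:
            [float(x) for x in rows[0]]
            header = False
        except ValueError:
            header = True
    names = [x.strip() for x in rows[0]] if header else None
    body = rows[1:] if header else rows
    try:
        values = np.array([[float(x) for x in row] for row in body])
    except ValueError as exc:
        raise GraphFormatError(f"{path}: non-numeric matrix entry") from exc
    return AdjacencyMatrix(values, names or list(range(len(body))))


def write_dense_csv(m: AdjacencyMatrix, path, header: bool = True) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if header:
            writer.writerow([str(u) for u in m.nodes])
        for row in m.values:
            writer.writerow([f"{x:g}" for x in row])


def read_matrix_market(path) -> AdjacencyMatrix:
    values = scipy.io.mmread(path)
    if scipy.sparse.issparse(values):
        values = values.toarray()
    return AdjacencyMatrix(np.asarray(values, dtype=float))


def write_matrix_market(m: AdjacencyMatrix, path) -> None:
    scipy.io.mmwrite(
        str(path), scipy.sparse.coo_matrix(m.values), comment="adjacency matrix"
    )
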