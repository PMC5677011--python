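"""Stage 1 — structural perturbation of the adjacency spectrum.

Any real square adjacency ``A`` splits exactly into a symmetric part
``A^S = (A + A^T)/2`` (average linking tendency) and an antisymmetric part
``A^AS = (A - A^T)/2`` (directional bias).  The structural perturbation
method treats a random subset of the observed links as a perturbation
``ΔA^S`` of the remainder ``R``: with ``R = Σ_k λ_k x_k x_k^T`` its spectral
form, first-order perturbation theory gives the eigenvalue shifts

    Δλ_k ≈ x_k^T ΔA^S x_k / (x_k^T x_k),

and the perturbed estimate keeps the eigenvectors fixed:

    Ã^S = Σ_k (λ_k + Δλ_k) x_k x_k^T.

Averaging Ã^S over independent perturbation-set draws and re-adding the
(untouched) antisymmetric part yields the final perturbed matrix
``Ã = Ã^S + A^AS`` used downstream.

Degenerate eigenvalues make the first-order formula basis-dependent; the
shifts are applied verbatim to the orthonormal basis LAPACK returns, and a
warning is logged whenever an eigen-gap falls below ``DEGENERACY_GAP``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .graph_core import AdjacencyMatrix, WeightedDigraph, from_adjacency, to_adjacency

logger = logging.getLogger("mpdlink")

__all__ = [
    "SymmetricDecomposition",
    "EigenSystem",
    "PerturbedMatrix",
    "symmetric_split",
    "eigen_decompose",
    "first_order_shifts",
    "spm_single",
    "spm_estimate",
]

#: eigen-gap below which the first-order shift formula is ill-conditioned
DEGENERACY_GAP = 1e-8
SYMMETRY_TOL = 1e-10


@dataclass
class SymmetricDecomposition:
    """The exact split A = A^S + A^AS."""

    symmetric_part: np.ndarray
    antisymmetric_part: np.ndarray


@dataclass
class EigenSystem:
    """Full real spectral decomposition, eigenvalues descending."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # column k pairs with eigenvalues[k]


@dataclass
class PerturbedMatrix:
    """The averaged perturbation estimate Ã."""

    values: np.ndarray
    n_selections: int
    perturbation_fraction: float


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, AdjacencyMatrix):
        return m.values
    return np.asarray(m, dtype=float)


def symmetric_split(m) -> SymmetricDecomposition:
    """Split into symmetric and antisymmetric parts; exact reconstruction."""
    a = _as_matrix(m)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("symmetric_split requires a square matrix")
    # (a+a.T)/2 is exactly symmetric and (a-a.T)/2 exactly antisymmetric in
    # floating point; their sum reconstructs a to machine precision
    return SymmetricDecomposition((a + a.T) / 2.0, (a - a.T) / 2.0)


def eigen_decompose(s) -> EigenSystem:
    """Spectral decomposition of a symmetric matrix, eigenvalues descending."""
    a = _as_matrix(s)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("eigen_decompose requires a square matrix")
    if np.max(np.abs(a - a.T), initial=0.0) > SYMMETRY_TOL:
        raise ValueError("eigen_decompose requires a symmetric matrix")
    w, v = np.linalg.eigh((a + a.T) / 2.0)
    order = np.argsort(w)[::-1]  # eigh is ascending; flip to descending
    w, v = w[order], v[:, order]
    gaps = np.abs(np.diff(w))
    if len(gaps) and gaps.min() < DEGENERACY_GAP:
        logger.warning(
            "near-degenerate spectrum (min eigen-gap %.2e); first-order "
            "shifts are basis-dependent", gaps.min(),
        )
    return EigenSystem(w, v)


def first_order_shifts(es: EigenSystem, delta) -> np.ndarray:
    """First-order eigenvalue shifts Δλ_k = x_k^T Δ x_k / (x_k^T x_k)."""
    d = _as_matrix(delta)
    n = es.eigenvectors.shape[0]
    if d.shape != (n, n):
        raise ValueError(f"delta shape {d.shape} does not match system size {n}")
    if np.max(np.abs(d - d.T), initial=0.0) > SYMMETRY_TOL:
        raise ValueError("delta must be symmetric")
    x = es.eigenvectors
    num = np.einsum("ik,ij,jk->k", x, d, x)
    den = np.einsum("ik,ik->k", x, x)
    return num / den


def spm_single(training: AdjacencyMatrix, perturbation_links) -> np.ndarray:
    """One perturbation pass: Ã^S = Σ (λ_k(R) + Δλ_k) x_k(R) x_k(R)^T.

    ``perturbation_links`` is a nonempty proper subset of the training graph's
    canonical link units; ``R`` is the symmetric part of the training matrix
    with those links removed, ``Δ`` the symmetric part of their adjacency.
    """
    directed = np.max(np.abs(training.values - training.values.T), initial=0.0) > 0
    g = from_adjacency(training, directed=directed)
    units = set(g.edge_units())
    psel = {tuple(p) for p in perturbation_links}
    if not psel:
        raise ValueError("perturbation set must be nonempty")
    if not psel <= units:
        raise ValueError("perturbation set must be a subset of training links")
    if psel == units:
        raise ValueError("perturbation set must be a proper subset (remainder empty)")

    index = training.node_index
    delta = np.zeros_like(training.values)
    for u, v in psel:
        # convention: entry (target, source); an undirected unit clears both
        delta[index[v], index[u]] = training.values[index[v], index[u]]
        if not directed:
            delta[index[u], index[v]] = training.values[index[u], index[v]]
    remainder = training.values - delta
    d_s = symmetric_split(delta).symmetric_part
    r_s = symmetric_split(remainder).symmetric_part
    es = eigen_decompose(r_s)
    shifts = first_order_shifts(es, d_s)
    x = es.eigenvectors
    return (x * (es.eigenvalues + shifts)) @ x.T


def spm_estimate(
    training: AdjacencyMatrix,
    fraction: float = 0.1,
    n_selections: int = 10,
    rng_seed: int = 0,
) -> PerturbedMatrix:
    """Averaged perturbation estimate Ã = mean(Ã^S over draws) + A^AS.

    Draws ``n_selections`` independent uniform subsets of the training links
    of size ``round(fraction * |links|)`` (at least 1), averages the single
    perturbation estimates, then adds the antisymmetric part of the full
    training matrix once.  For undirected inputs a link unit is the unordered
    pair, so removing it clears both matrix entries.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    if n_selections < 1:
        raise ValueError("n_selections must be positive")
    directed = np.max(np.abs(training.values - training.values.T), initial=0.0) > 0
    g = from_adjacency(training, directed=directed)
    units = g.edge_units()
    if len(units) < 2:
        raise ValueError("training graph must have at least 2 links")
    k = max(1, int(np.floor(fraction * len(units) + 0.5)))
    if k >= len(units):
        k = len(units) - 1
    rng = np.random.default_rng(rng_seed)
    acc = np.zeros_like(training.values)
    for _ in range(n_selections):
        pick = rng.choice(len(units), size=k, replace=False)
        acc += spm_single(training, [units[i] for i in pick])
    avg = acc / n_selections
    a_as = symmetric_split(training.values).antisymmetric_part
    return PerturbedMatrix(avg + a_as, n_selections, fraction)
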