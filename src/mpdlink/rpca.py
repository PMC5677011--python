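"""Stage 2 — robust-PCA split of the perturbed matrix.

The perturbed matrix Ã is modelled as a low-rank backbone Ã_B (the regular
organisation of the network) plus sparse noise Ã_N.  The ideal program
``min rank(Ã_B) + γ‖Ã_N‖_0  s.t.  Ã = Ã_B + Ã_N`` is NP-hard and is never
solved here; the implemented surrogate is its standard convex relaxation

    min ‖Ã_B‖_* + λ‖Ã_N‖_1   subject to   Ã = Ã_B + Ã_N,

solved by the inexact augmented-Lagrangian method (IALM): alternate
singular-value thresholding on the backbone and elementwise soft
thresholding on the noise, with a dual matrix Y and an increasing penalty μ.

Solver constants follow the standard IALM choices for this formulation:
``μ0 = 1.25/‖m‖_2`` (spectral norm), ``ρ = 1.5``,
``Y0 = m / max(‖m‖_2, ‖m‖_∞/λ)``, tolerance 1e-7 on the relative Frobenius
constraint violation, 1000 iterations cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("mpdlink")

__all__ = [
    "RpcaResult",
    "soft_threshold",
    "singular_value_threshold",
    "rpca_decompose",
    "lambda_sweep",
    "default_lambda_grid",
]

DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 1000
RHO = 1.5


def default_lambda_grid() -> np.ndarray:
    """The sweep grid 0.01, 0.02, ..., 0.39."""
    return np.round(np.arange(1, 40) * 0.01, 2)


@dataclass
class RpcaResult:
    backbone: np.ndarray
    noise: np.ndarray
    lambda_param: float
    iterations: int
    converged: bool
    residual: float  # final relative Frobenius constraint violation


def soft_threshold(m, tau: float) -> np.ndarray:
    """Elementwise shrinkage sign(x)·max(|x|−τ, 0) — the l1 proximal map."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    a = np.asarray(m, dtype=float)
    return np.sign(a) * np.maximum(np.abs(a) - tau, 0.0)


def singular_value_threshold(m, tau: float) -> np.ndarray:
    """Shrink the singular values by τ — the nuclear-norm proximal map."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    u, s, vt = np.linalg.svd(np.asarray(m, dtype=float), full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    return (u[:, keep] * s[keep]) @ vt[keep]


def rpca_decompose(
    m,
    lambda_param: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RpcaResult:
    """Split ``m`` into backbone + noise by inexact ALM.

    Deterministic for fixed input.  Non-convergence within ``max_iter``
    returns the current iterate with ``converged=False`` and logs a warning.
    """
    a = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("input matrix must be finite")
    if lambda_param <= 0:
        raise ValueError("lambda_param must be positive")
    norm_fro = np.linalg.norm(a)
    if norm_fro == 0.0:
        return RpcaResult(np.zeros_like(a), np.zeros_like(a), lambda_param, 1, True, 0.0)

    norm_two = np.linalg.norm(a, 2)
    norm_inf = np.abs(a).max()
    y = a / max(norm_two, norm_inf / lambda_param)
    mu = 1.25 / norm_two
    backbone = np.zeros_like(a)
    noise = np.zeros_like(a)
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        backbone = singular_value_threshold(a - noise + y / mu, 1.0 / mu)
        noise = soft_threshold(a - backbone + y / mu, lambda_param / mu)
        gap = a - backbone - noise
        y = y + mu * gap
        mu *= RHO
        residual = np.linalg.norm(gap) / norm_fro
        if residual < tol:
            return RpcaResult(backbone, noise, lambda_param, it, True, residual)
    logger.warning(
        "rpca_decompose: no convergence in %d iterations (residual %.2e)",
        max_iter, residual,
    )
    return RpcaResult(backbone, noise, lambda_param, it, False, residual)


def lambda_sweep(m, grid, evaluator):
    """Run :func:`rpca_decompose` over a λ grid and score each result.

    Returns ``(best_lambda, scores)`` where ``scores`` maps λ to the
    evaluator's value; ties resolve to the smallest λ.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("lambda grid must be nonempty")
    scores = {}
    for lam in grid:
        scores[float(lam)] = float(evaluator(rpca_decompose(m, float(lam))))
    best = max(sorted(scores), key=lambda lam: (scores[lam], -lam))
    return best, scores
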