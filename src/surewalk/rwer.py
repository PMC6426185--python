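"""Random walk with node-specific restart probabilities (RWER).

A random surfer on a graph with row-stochastic transition matrix
``A_tilde`` carries a length-n restart vector ``c``: sitting at node v it
follows an out-edge with probability ``1 - c[v]`` and teleports to the
seed distribution ``q`` with probability ``c[v]``.  The stationary score
vector ``r`` satisfies the fixed point

    r = A_tilde^T (I - diag(c)) r + (c^T r) q

which, using ``1^T r = 1``, has the closed form ``r = (I - B)^{-1} q``
with ``B = A_tilde^T (I - diag(c)) + q (c - 1)^T``.  A constant restart
vector recovers the classical random walk with restart (personalized
PageRank with a single seed).

The iterative solver is plain power iteration (one sparse matrix-vector
product per step, O(m) per iteration).  The dense closed form is provided
as an oracle for small graphs.

Dangling nodes (zero out-degree) are given the policy: the surfer at a
dangling node teleports to the seed distribution with probability 1, i.e.
dangling rows of ``A_tilde`` are replaced by ``q^T``.  This keeps the walk
operator column-stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import scipy.sparse as sp

from .graph_io import RowStochasticMatrix

__all__ = [
    "ScoreVector",
    "ConvergenceError",
    "seed_vector",
    "restart_vector",
    "validate_restart",
    "effective_transition",
    "rwer_power",
    "rwer_closed_form",
    "rwr",
    "transition_operator",
    "build_b_dense",
    "dense_resolvent",
]

#: largest n for which dense closed-form paths are allowed
DENSE_GUARD = 2000

#: per-iteration renormalization guard against floating-point drift
_MASS_TOL = 1e-12


class ConvergenceError(RuntimeError):
    """Power iteration or linear solve failed to reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass
class ScoreVector:
    """Stationary scores plus solver diagnostics.

    ``r`` is non-negative and sums to 1 (within 1e-9); ``iterations`` is
    the number of power-iteration steps (0 for the closed form);
    ``residual`` is the final L1 change, or the closed-form backward error.
    """

    r: np.ndarray
    iterations: int
    residual: float


def seed_vector(n: int, seeds: int | Iterable[int]) -> np.ndarray:
    """Uniform distribution over a seed node or seed set."""
    if np.isscalar(seeds):
        seeds = [int(seeds)]
    seeds = sorted({int(s) for s in seeds})
    if not seeds:
        raise ValueError("seed set is empty")
    for s in seeds:
        if not 0 <= s < n:
            raise ValueError(f"seed node {s} outside [0, {n})")
    q = np.zeros(n)
    q[seeds] = 1.0 / len(seeds)
    return q


def restart_vector(n: int, value: float | np.ndarray) -> np.ndarray:
    """Broadcast a scalar restart probability to a length-n vector."""
    c = np.broadcast_to(np.asarray(value, dtype=np.float64), (n,)).copy()
    validate_restart(c)
    return c


def validate_restart(c: np.ndarray, c_min: float = 0.0, c_max: float = 1.0) -> None:
    c = np.asarray(c)
    if c.ndim != 1:
        raise ValueError("restart vector must be one-dimensional")
    if np.any(c < c_min) or np.any(c > c_max):
        raise ValueError(f"restart probabilities must lie in [{c_min}, {c_max}]")


def effective_transition(At: RowStochasticMatrix, q: np.ndarray) -> sp.csr_matrix:
    """Row-stochastic transition matrix with dangling rows replaced by q^T."""
    if At.dangling.size == 0:
        return At.matrix
    n = At.n
    rows = np.repeat(At.dangling, np.count_nonzero(q))
    cols = np.tile(np.flatnonzero(q), At.dangling.size)
    data = np.tile(q[q > 0], At.dangling.size)
    patch = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
    return sp.csr_matrix(At.matrix + patch)


def rwer_power(
    At: RowStochasticMatrix,
    q: np.ndarray,
    c: np.ndarray,
    eps: float = 1e-10,
    max_iter: int = 1000,
) -> ScoreVector:
    """Solve the restart fixed point by power iteration.

    Iterates ``r' = A_tilde^T ((1-c) * r) + (c . r) q`` from ``r0 = q``
    until the L1 change drops below ``eps``.  The iterate is renormalized
    to unit mass whenever floating-point drift exceeds 1e-12.

    Raises
    ------
    ConvergenceError
        If ``max_iter`` steps do not reach ``eps``; the exception carries
        the last residual.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    validate_restart(c)
    n = At.n
    if q.shape != (n,) or c.shape != (n,):
        raise ValueError("q and c must be length-n vectors")
    T = sp.csr_matrix(effective_transition(At, q).T)
    keep = 1.0 - c
    r = q.copy()
    for it in range(1, max_iter + 1):
        r_new = T @ (keep * r) + (c @ r) * q
        delta = float(np.abs(r_new - r).sum())
        r = r_new
        mass = r.sum()
        if abs(mass - 1.0) > _MASS_TOL:
            r = r / mass
        if delta < eps:
            return ScoreVector(r=r, iterations=it, residual=delta)
    raise ConvergenceError(
        f"power iteration did not converge in {max_iter} iterations "
        f"(last residual {delta:.3e})",
        residual=delta,
    )


def build_b_dense(At: RowStochasticMatrix, q: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Dense ``B = A_tilde^T (I - diag(c)) + q (c - 1)^T`` (dangling-fixed)."""
    a_eff = effective_transition(At, q).toarray()
    return a_eff.T * (1.0 - c)[np.newaxis, :] + np.outer(q, c - 1.0)


def rwer_closed_form(
    At: RowStochasticMatrix,
    q: np.ndarray,
    c: np.ndarray,
    dense_guard: int = DENSE_GUARD,
) -> ScoreVector:
    """Exact stationary scores via the dense linear system (I - B) r = q.

    Intended as an oracle on small graphs; guarded by ``dense_guard``.
    """
    validate_restart(c)
    n = At.n
    if n > dense_guard:
        raise ValueError(f"closed form limited to n <= {dense_guard} (got n={n})")
    A = np.eye(n) - build_b_dense(At, q, c)
    try:
        r = np.linalg.solve(A, q)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - Lemma-2 guarded
        raise ConvergenceError(f"closed-form system is singular: {exc}") from exc
    residual = float(np.linalg.norm(A @ r - q))
    return ScoreVector(r=r, iterations=0, residual=residual)


def rwr(
    At: RowStochasticMatrix,
    q: np.ndarray,
    c_scalar: float,
    eps: float = 1e-10,
    max_iter: int = 1000,
) -> ScoreVector:
    """Classical random walk with restart: constant restart probability."""
    if not 0.0 <= c_scalar <= 1.0:
        raise ValueError("restart probability must lie in [0, 1]")
    return rwer_power(At, q, restart_vector(At.n, c_scalar), eps=eps, max_iter=max_iter)


def transition_operator(
    At: RowStochasticMatrix, q: np.ndarray, c: np.ndarray
) -> sp.csr_matrix:
    """Column-stochastic walk operator ``G = A_tilde^T (I - diag(c)) + q c^T``.

    ``r`` is the principal eigenvector of ``G``; every column sums to 1
    because transition mass at node j splits into ``1 - c[j]`` edge-follow
    and ``c[j]`` teleport.
    """
    validate_restart(c)
    a_eff = effective_transition(At, q)
    G = sp.csr_matrix(a_eff.T) @ sp.diags(1.0 - c)
    q_sp = sp.csr_matrix(q.reshape(-1, 1))
    c_sp = sp.csr_matrix(c.reshape(1, -1))
    return sp.csr_matrix(G + q_sp @ c_sp)


def dense_resolvent(
    At: RowStochasticMatrix,
    q: np.ndarray,
    c: np.ndarray,
    dense_guard: int = DENSE_GUARD,
) -> np.ndarray:
    """Dense resolvent ``M = (I - B)^{-1}`` (oracle for gradients/tests).

    ``M[:, s]`` is the score vector for seed ``s``; the matrix is only
    formed for small n.
    """
    n = At.n
    if n > dense_guard:
        raise ValueError(f"dense resolvent limited to n <= {dense_guard} (got n={n})")
    return np.linalg.inv(np.eye(n) - build_b_dense(At, q, c))
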