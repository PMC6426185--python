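"""Supervised learning of the restart vector from labeled node pairs.

Given a query node ``s`` with positive nodes P (nodes the query prefers)
and negative nodes N, the restart vector ``c`` is fit by minimizing

    F(c) = lambda * ||c - o||^2  +  sum_{x in P, y in N} h(r_y - r_x)

where ``r`` is the stationary score vector of the walk under ``c``,
``o`` is an origin (regularization anchor) vector, and
``h(x) = 1 / (1 + exp(-x / b))`` is a sharpened sigmoid surrogate for the
pairwise 0/1 ranking loss: driving positives' scores above negatives'
drives each pair term toward 0.

The gradient avoids forming the resolvent ``M = (I - B)^{-1}``:

    dF/dc = 2 lambda (c - o) + ((-A_tilde + 1 e_s^T) r_adj) .* r

where ``r_adj`` solves the adjoint linear system
``(I - B^T) r_adj = p`` and ``p = sum_{x,y} h'(r_y - r_x) (e_y - e_x)``
aggregates the per-pair loss slopes on the labeled nodes.  The adjoint
system is solved with GMRES (the matrix is non-symmetric), with a dense
fallback on small graphs.

Optimization is projected gradient descent: after each step ``c`` is
clamped to ``[c_min, c_max]`` so it remains a valid probability vector,
with optional step halving when a step would increase the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import expit

from .graph_io import Graph, LabelSet, RowStochasticMatrix, row_normalize
from .rwer import (
    ConvergenceError,
    ScoreVector,
    build_b_dense,
    effective_transition,
    rwer_power,
    seed_vector,
    validate_restart,
)

__all__ = [
    "TrainingInstance",
    "LearnConfig",
    "LearnResult",
    "DivergenceError",
    "loss_h",
    "loss_h_prime",
    "cost_F",
    "build_p_tilde",
    "solve_r_tilde",
    "gradient_F",
    "grad_score_dense",
    "learn_restart",
]


class DivergenceError(RuntimeError):
    """Gradient descent kept increasing the cost; try a smaller learning rate."""


@dataclass(frozen=True)
class TrainingInstance:
    """A query node with its positive and negative side-information sets."""

    seed: int
    positives: tuple[int, ...]
    negatives: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positives", tuple(sorted({int(i) for i in self.positives})))
        object.__setattr__(self, "negatives", tuple(sorted({int(i) for i in self.negatives})))
        if set(self.positives) & set(self.negatives):
            raise ValueError("positive and negative sets overlap")
        if self.seed in self.positives or self.seed in self.negatives:
            raise ValueError("query node must not be labeled")

    @classmethod
    def from_labels(cls, seed: int, labels: LabelSet) -> "TrainingInstance":
        labels.validate_for_query(seed)
        return cls(seed=seed, positives=tuple(labels.positives),
                   negatives=tuple(labels.negatives))


@dataclass
class LearnConfig:
    """Hyperparameters of the restart-vector learner.

    Defaults: ``lam=1`` and ``b=0.01`` (grid-search winners in the ranking
    and link-prediction experiments this learner targets); the origin is
    the conventional constant restart 0.15.  ``b`` controls how sharply
    the sigmoid loss approximates the 0/1 pairwise ranking loss — scores
    differing by a few multiples of ``b`` already saturate the pair term.
    """

    lam: float = 1.0
    b: float = 1e-2
    origin: float | np.ndarray = 0.15
    eta: float = 0.1
    inner_eps: float = 1e-10
    inner_max_iter: int = 20000
    solver_eps: float = 1e-8
    outer_eps: float = 1e-4
    max_outer: int = 200
    c_min: float = 1e-3
    c_max: float = 0.999
    rng_seed: int = 0
    init: str = "random"          # "random" (uniform in clamp range) or "origin"
    halving: bool = True          # halve the step while the cost would increase
    max_halvings: int = 30
    divergence_patience: int = 5  # consecutive accepted cost increases -> error

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.b <= 0:
            raise ValueError("b must be > 0")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if not 0.0 < self.c_min < self.c_max < 1.0:
            raise ValueError("need 0 < c_min < c_max < 1")
        if self.init not in ("random", "origin"):
            raise ValueError("init must be 'random' or 'origin'")

    def origin_vector(self, n: int) -> np.ndarray:
        o = np.broadcast_to(np.asarray(self.origin, dtype=np.float64), (n,)).copy()
        return o

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LearnConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {}
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            d[name] = v.tolist() if isinstance(v, np.ndarray) else v
        return d


@dataclass
class LearnResult:
    """Learned restart vector with the optimization trace."""

    c: np.ndarray
    cost_trace: list[float]
    iterations: int
    converged: bool
    final_scores: np.ndarray = field(default=None, repr=False)


def loss_h(x, b: float):
    """Sigmoid ranking loss ``h(x) = 1 / (1 + exp(-x/b))``, overflow-safe."""
    if b <= 0:
        raise ValueError("b must be > 0")
    return expit(np.asarray(x, dtype=np.float64) / b)


def loss_h_prime(x, b: float):
    """Derivative ``h'(x) = h(x) (1 - h(x)) / b`` (saturates to 0 for |x| >> b)."""
    h = loss_h(x, b)
    return h * (1.0 - h) / b


def _pair_deltas(r: np.ndarray, instance: TrainingInstance) -> np.ndarray:
    """Matrix of score gaps ``delta[j, i] = r_y_j - r_x_i`` over N x P."""
    rP = r[list(instance.positives)]
    rN = r[list(instance.negatives)]
    return rN[:, None] - rP[None, :]


def _scores(c, instance, config, At) -> ScoreVector:
    q = seed_vector(At.n, instance.seed)
    return rwer_power(At, q, c, eps=config.inner_eps, max_iter=config.inner_max_iter)


def cost_F(
    c: np.ndarray,
    instance: TrainingInstance,
    config: LearnConfig,
    At: RowStochasticMatrix,
    scores: np.ndarray | None = None,
) -> float:
    """Evaluate the regularized pairwise ranking cost at ``c``.

    ``scores`` may be supplied to reuse an already computed score vector.
    """
    validate_restart(c)
    r = _scores(c, instance, config, At).r if scores is None else scores
    o = config.origin_vector(At.n)
    reg = config.lam * float(np.sum((c - o) ** 2))
    if not instance.positives or not instance.negatives:
        return reg
    return reg + float(loss_h(_pair_deltas(r, instance), config.b).sum())


def build_p_tilde(instance: TrainingInstance, r: np.ndarray, b: float) -> np.ndarray:
    """Aggregate per-pair loss slopes onto the labeled nodes.

    ``p = sum_{x in P, y in N} h'(r_y - r_x) (e_y - e_x)``; the entries
    sum to zero exactly because each pair contributes +w at y and -w at x.
    """
    p = np.zeros_like(r)
    if not instance.positives or not instance.negatives:
        return p
    W = loss_h_prime(_pair_deltas(r, instance), b)  # |N| x |P|
    np.add.at(p, list(instance.negatives), W.sum(axis=1))
    np.add.at(p, list(instance.positives), -W.sum(axis=0))
    return p


def solve_r_tilde(
    At: RowStochasticMatrix,
    c: np.ndarray,
    q: np.ndarray,
    p_tilde: np.ndarray,
    solver_eps: float = 1e-8,
    dense_guard: int = 2000,
) -> np.ndarray:
    """Solve the adjoint system ``(I - B^T) r_adj = p`` with GMRES.

    ``B^T v = (1-c) * (A_tilde v) + (c-1) (q . v)`` is applied matrix-free,
    so one GMRES iteration costs one sparse matrix-vector product.  On
    breakdown (or insufficient residual) a dense solve is used when
    ``n <= dense_guard``.
    """
    n = At.n
    a_eff = sp.csr_matrix(effective_transition(At, q))
    keep = 1.0 - c

    def matvec(v):
        return v - (keep * (a_eff @ v) + (c - 1.0) * (q @ v))

    op = spla.LinearOperator((n, n), matvec=matvec, dtype=np.float64)
    x, info = spla.gmres(op, p_tilde, rtol=0.0, atol=0.25 * solver_eps,
                         restart=min(n, 200), maxiter=max(50, 4 * n))
    resid = float(np.linalg.norm(matvec(x) - p_tilde))
    if info == 0 and resid < solver_eps:
        return x
    if n <= dense_guard:
        A = np.eye(n) - build_b_dense(At, q, c)
        x = np.linalg.solve(A.T, p_tilde)
        resid = float(np.linalg.norm(matvec(x) - p_tilde))
        if resid < solver_eps:
            return x
    raise ConvergenceError(
        f"adjoint solve residual {resid:.3e} above tolerance {solver_eps:.1e}",
        residual=resid,
    )


def gradient_F(
    c: np.ndarray,
    instance: TrainingInstance,
    config: LearnConfig,
    At: RowStochasticMatrix,
    scores: np.ndarray | None = None,
) -> np.ndarray:
    """Analytic gradient of the cost with respect to the restart vector.

    Assembles ``2 lambda (c - o) + ((-A_tilde + 1 e_s^T) r_adj) .* r``
    from one forward walk solve and one adjoint linear solve.
    """
    validate_restart(c)
    n = At.n
    o = config.origin_vector(n)
    grad = 2.0 * config.lam * (c - o)
    if not instance.positives or not instance.negatives:
        return grad
    q = seed_vector(n, instance.seed)
    r = _scores(c, instance, config, At).r if scores is None else scores
    p = build_p_tilde(instance, r, config.b)
    r_adj = solve_r_tilde(At, c, q, p, solver_eps=config.solver_eps)
    a_eff = sp.csr_matrix(effective_transition(At, q))
    pair_term = (-(a_eff @ r_adj) + r_adj[instance.seed]) * r
    return grad + pair_term


def grad_score_dense(
    M: np.ndarray,
    x: int,
    s: int,
    At: RowStochasticMatrix,
    q: np.ndarray,
) -> np.ndarray:
    """Dense derivative of a single score ``r_x`` w.r.t. every restart entry.

    ``d r_x / dc = ((-A_tilde + 1 e_s^T) M[x, :]^T) .* M[:, s]`` — an
    oracle path used to validate the assembled gradient on small graphs.
    """
    a_eff = effective_transition(At, q).toarray()
    mx = M[x, :]
    return (-(a_eff @ mx) + mx[s]) * M[:, s]


def learn_restart(
    graph: Graph | RowStochasticMatrix,
    instance: TrainingInstance,
    config: LearnConfig | None = None,
) -> LearnResult:
    """Fit the restart vector by projected gradient descent.

    Starts from a uniform-random vector in the clamp range (or the origin,
    per ``config.init``), takes gradient steps of size ``eta`` — halving
    the step while it would increase the cost when ``config.halving`` —
    and clamps each iterate into ``[c_min, c_max]``.  Stops when the
    infinity-norm change of ``c`` drops below ``outer_eps`` or after
    ``max_outer`` iterations.  The run is a pure function of
    ``(graph, instance, config)`` including ``rng_seed``.

    Raises
    ------
    DivergenceError
        If the accepted cost increases ``divergence_patience`` times in a
        row (only reachable with ``halving=False``).
    """
    config = config or LearnConfig()
    if not instance.positives or not instance.negatives:
        raise ValueError("learning requires non-empty positive and negative sets")
    At = graph if isinstance(graph, RowStochasticMatrix) else row_normalize(graph)
    n = At.n
    for node in (instance.seed, *instance.positives, *instance.negatives):
        if not 0 <= node < n:
            raise ValueError(f"node {node} outside [0, {n})")
    rng = np.random.default_rng(config.rng_seed)
    if config.init == "random":
        c = rng.uniform(config.c_min, config.c_max, size=n)
    else:
        c = np.clip(config.origin_vector(n), config.c_min, config.c_max)

    sv = _scores(c, instance, config, At)
    cost = cost_F(c, instance, config, At, scores=sv.r)
    trace = [cost]
    converged = False
    bad_steps = 0
    it = 0
    for it in range(1, config.max_outer + 1):
        grad = gradient_F(c, instance, config, At, scores=sv.r)
        step = config.eta
        halvings = 0
        while True:
            c_new = np.clip(c - step * grad, config.c_min, config.c_max)
            sv_new = _scores(c_new, instance, config, At)
            cost_new = cost_F(c_new, instance, config, At, scores=sv_new.r)
            if (config.halving and cost_new > cost
                    and halvings < config.max_halvings
                    and not np.array_equal(c_new, c)):
                step *= 0.5
                halvings += 1
                continue
            break
        delta_c = float(np.max(np.abs(c_new - c)))
        c, sv = c_new, sv_new
        if cost_new > cost:
            bad_steps += 1
            if bad_steps >= config.divergence_patience:
                raise DivergenceError(
                    f"cost increased {bad_steps} consecutive iterations; "
                    f"reduce the learning rate (eta={config.eta})"
                )
        else:
            bad_steps = 0
        cost = cost_new
        trace.append(cost)
        if delta_c < config.outer_eps:
            converged = True
            break
    return LearnResult(c=c, cost_trace=trace, iterations=it,
                       converged=converged, final_scores=sv.r)


def write_restart_vector(c: np.ndarray, path: str | Path,
                         inverse_map=None) -> None:
    """Write the learned restart vector as ``node-id  c_i`` TSV."""
    inv = inverse_map or {}
    with open(path, "w") as fh:
        for i, v in enumerate(np.asarray(c, dtype=np.float64)):
            fh.write(f"{inv.get(i, i)}\t{v:.17g}\n")


def read_restart_vector(path: str | Path, n: int, id_map=None) -> np.ndarray:
    """Read a restart-vector TSV; every node in [0, n) must be present."""
    from .graph_io import GraphFormatError, _parse_node_token

    c = np.full(n, np.nan)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise GraphFormatError(f"{path}:{lineno}: expected 'node c_i'")
            raw = _parse_node_token(parts[0])
            idx = id_map[raw] if id_map else int(raw)
            if not 0 <= idx < n:
                raise GraphFormatError(f"{path}:{lineno}: node {raw!r} outside [0, {n})")
            c[idx] = float(parts[1])
    missing = np.flatnonzero(np.isnan(c))
    if missing.size:
        raise GraphFormatError(
            f"{path}: missing restart probability for node {int(missing[0])}"
        )
    return c
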