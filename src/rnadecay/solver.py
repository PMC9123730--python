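"""l1-regularized non-negative least squares for the pairwise systems.

Each pair system asks for

    argmin_{theta >= 0}  ||A theta - y||_2^2 + alpha * sum_i theta_i

with theta in R^3.  On the non-negative orthant the l1 penalty is linear,
so the problem is a tiny convex quadratic program.  Its global minimizer is
found exactly by enumerating the 8 zero/free patterns of theta: for each
support S the stationary point solves the reduced normal equations
G_S theta_S = (A'y - alpha/2)_S in closed form, and the best feasible
candidate is the global optimum.  Each solve costs a handful of arithmetic
operations, which is what makes the m(m-1) problems of a full dataset
tractable; the routine is vectorized over batches of systems represented by
their Gram matrices.

Half-lives follow from the parameter vector as h = ln2 * theta1 / theta2
(theta1 is the promoter scale ratio, theta2 that ratio times the decay
rate); when either entry is zero the half-life is undefined and the
estimate is flagged invalid.

The single regularization weight alpha shared by all systems of a dataset
is chosen by the L-curve method: the corner (point of maximum curvature) of
the mean log residual-norm vs mean log solution-norm curve over a sample of
systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pairsys import PairSystem, build_pair_system
from .timeseries import ExpressionTimeSeries

__all__ = [
    "ThetaEstimate",
    "RegularizationConfig",
    "default_alpha_grid",
    "solve_l1_nnls",
    "solve_gram_batch",
    "kkt_residual",
    "halflife_from_theta",
    "lcurve_select_alpha",
    "estimate_pair",
]

LN2 = float(np.log(2.0))

# supports in lexicographic order; ties in objective and l1 norm resolve to
# the earliest entry
_SUPPORTS: tuple[tuple[int, ...], ...] = (
    (),
    (0,),
    (0, 1),
    (0, 1, 2),
    (0, 2),
    (1,),
    (1, 2),
    (2,),
)

_DET_RTOL = 1e-13  # relative determinant threshold for a solvable support
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class ThetaEstimate:
    """Solution of one pair system: parameters, fit error, half-life."""

    theta: np.ndarray
    q: float
    halflife: float  # NaN when invalid
    valid: bool


@dataclass
class RegularizationConfig:
    """How the global regularization weight alpha is selected."""

    alpha_grid: np.ndarray = field(default_factory=lambda: default_alpha_grid())
    alpha_opt: float | None = None
    pair_subsample: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.alpha_grid, dtype=float)
        if grid.ndim != 1 or grid.size == 0 or np.any(grid <= 0):
            raise ValueError("alpha_grid must be a non-empty positive vector")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("alpha_grid must be sorted ascending")
        self.alpha_grid = grid


def default_alpha_grid(lo: float = 1e-2, hi: float = 1e3, num: int = 25) -> np.ndarray:
    """Log-spaced candidate grid for the regularization weight."""
    if not (0 < lo < hi) or num < 1:
        raise ValueError("need 0 < lo < hi and num >= 1")
    return np.logspace(np.log10(lo), np.log10(hi), num)


def _pair_solution(G, bp, k, l):
    """Stationary point on support {k, l}; returns (tk, tl, solvable)."""
    a, d, c = G[:, k, k], G[:, l, l], G[:, k, l]
    det = a * d - c * c
    solvable = det > _DET_RTOL * np.maximum(a * d, np.finfo(float).tiny)
    safe = np.where(solvable, det, 1.0)
    tk = (d * bp[:, k] - c * bp[:, l]) / safe
    tl = (a * bp[:, l] - c * bp[:, k]) / safe
    return tk, tl, solvable


def _full_solution(G, bp):
    """Stationary point on the full support via the adjugate of G."""
    g00, g01, g02 = G[:, 0, 0], G[:, 0, 1], G[:, 0, 2]
    g11, g12, g22 = G[:, 1, 1], G[:, 1, 2], G[:, 2, 2]
    c00 = g11 * g22 - g12 * g12
    c01 = g02 * g12 - g01 * g22
    c02 = g01 * g12 - g02 * g11
    c11 = g00 * g22 - g02 * g02
    c12 = g01 * g02 - g00 * g12
    c22 = g00 * g11 - g01 * g01
    det = g00 * c00 + g01 * c01 + g02 * c02
    diag_prod = g00 * g11 * g22
    solvable = det > _DET_RTOL * np.maximum(diag_prod, np.finfo(float).tiny)
    safe = np.where(solvable, det, 1.0)
    t0 = (c00 * bp[:, 0] + c01 * bp[:, 1] + c02 * bp[:, 2]) / safe
    t1 = (c01 * bp[:, 0] + c11 * bp[:, 1] + c12 * bp[:, 2]) / safe
    t2 = (c02 * bp[:, 0] + c12 * bp[:, 1] + c22 * bp[:, 2]) / safe
    return np.stack([t0, t1, t2], axis=1), solvable


def solve_gram_batch(
    G: np.ndarray, b: np.ndarray, yty: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve a batch of 3-variable l1-regularized NNLS problems exactly.

    Parameters are the normal-equation ingredients of each system:
    ``G = A'A`` (N x 3 x 3), ``b = A'y`` (N x 3) and ``yty = y'y`` (N,).

    Returns ``(theta, q, obj)`` with the squared residual ``q`` (penalty
    excluded) and the full objective value per system.
    """
    G = np.asarray(G, dtype=float)
    b = np.atleast_2d(np.asarray(b, dtype=float))
    yty = np.atleast_1d(np.asarray(yty, dtype=float))
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    n = b.shape[0]
    bp = b - 0.5 * alpha  # linear term of the orthant-restricted QP

    best_theta = np.zeros((n, 3))
    best_obj = yty.copy()  # empty support: theta = 0
    best_l1 = np.zeros(n)

    for support in _SUPPORTS[1:]:
        theta = np.zeros((n, 3))
        if len(support) == 1:
            (k,) = support
            g = G[:, k, k]
            solvable = g > 0
            theta[:, k] = bp[:, k] / np.where(solvable, g, 1.0)
        elif len(support) == 2:
            k, l = support
            tk, tl, solvable = _pair_solution(G, bp, k, l)
            theta[:, k], theta[:, l] = tk, tl
        else:
            theta, solvable = _full_solution(G, bp)
        feasible = solvable & np.all(theta[:, support] >= 0, axis=1)
        if not np.any(feasible):
            continue
        quad = np.einsum("ni,nij,nj->n", theta, G, theta)
        q = yty - 2.0 * np.einsum("ni,ni->n", b, theta) + quad
        l1 = theta.sum(axis=1)
        obj = q + alpha * l1
        tie = _TIE_RTOL * (1.0 + np.abs(best_obj))
        better = obj < best_obj - tie
        tied = (~better) & (np.abs(obj - best_obj) <= tie) & (l1 < best_l1 - tie)
        take = feasible & (better | tied)
        if np.any(take):
            best_theta[take] = theta[take]
            best_obj[take] = obj[take]
            best_l1[take] = l1[take]

    q_best = np.maximum(best_obj - alpha * best_l1, 0.0)
    return best_theta, q_best, best_obj


def kkt_residual(G: np.ndarray, b: np.ndarray, alpha: float, theta: np.ndarray) -> float:
    """Max violation of the KKT optimality conditions at ``theta``.

    Zero (to numerical precision) certifies global optimality of the convex
    program: the gradient vanishes on free coordinates and is non-negative
    on active (zero) coordinates.
    """
    grad = 2.0 * (G @ theta - b) + alpha
    scale = 1.0 + np.abs(grad).max()
    free = theta > 1e-9 * (1.0 + theta.max(initial=0.0))
    r = 0.0
    if np.any(free):
        r = float(np.abs(grad[free]).max())
    if np.any(~free):
        r = max(r, float(np.maximum(-grad[~free], 0.0).max()))
    return r / scale


def solve_l1_nnls(A: np.ndarray, y: np.ndarray, alpha: float) -> ThetaEstimate:
    """Global minimizer of ||A theta - y||^2 + alpha*sum(theta), theta >= 0.

    ``q`` in the returned estimate is the pure squared residual at the
    solution; the penalty term is excluded.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    if A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("A must be a (rows x 3) matrix")
    if y.shape != (A.shape[0],):
        raise ValueError("y length must match the number of rows of A")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(y)) and np.isfinite(alpha)):
        raise ValueError("A, y and alpha must be finite")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 rows (intervals) to fit 3 parameters")
    if A.shape[0] == 3:
        warnings.warn(
            "system has exactly as many rows as unknowns; estimates may be "
            "unreliable (5 or more time points are recommended)",
            stacklevel=2,
        )
    G = (A.T @ A)[None]
    b = (A.T @ y)[None]
    yty = np.array([float(y @ y)])
    theta, q, _ = solve_gram_batch(G, b, yty, alpha)
    theta = theta[0]
    h = halflife_from_theta(theta)
    return ThetaEstimate(theta, float(q[0]), h, bool(np.isfinite(h)))


def halflife_from_theta(theta) -> float:
    """h = ln2 * theta1 / theta2, or NaN when either entry is zero.

    theta1 is the promoter scale ratio and theta2 is that ratio times the
    decay rate, so the decay rate itself never has to be isolated.  A zero
    theta2 corresponds to an infinite half-life and is reported as
    undefined rather than an error.
    """
    theta = np.asarray(theta, dtype=float)
    if theta[0] > 0 and theta[1] > 0:
        return LN2 * theta[0] / theta[1]
    return float("nan")


def _systems_to_gram(systems: list[PairSystem]):
    G = np.stack([s.A.T @ s.A for s in systems])
    b = np.stack([s.A.T @ s.y for s in systems])
    yty = np.array([float(s.y @ s.y) for s in systems])
    return G, b, yty


def lcurve_select_alpha(systems: list[PairSystem], alpha_grid) -> float:
    """Select alpha at the corner of the L-curve over a sample of systems.

    For every alpha on the grid the mean (over systems) log residual norm
    and mean log solution l1-norm are computed; the corner is the grid
    point of maximum discrete curvature of that log-log curve, with ties
    broken toward larger alpha (stronger regularization).
    """
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if len(systems) == 0 or alpha_grid.size == 0:
        raise ValueError("need at least one system and one grid point")
    if all(np.allclose(s.y, 0.0) for s in systems):
        raise ValueError("all responses are zero; the L-curve is degenerate")
    if alpha_grid.size == 1:
        return float(alpha_grid[0])

    G, b, yty = _systems_to_gram(systems)
    floor = 1e-30
    xs = np.empty(alpha_grid.size)
    ys = np.empty(alpha_grid.size)
    for k, alpha in enumerate(alpha_grid):
        theta, q, _ = solve_gram_batch(G, b, yty, float(alpha))
        l1 = theta.sum(axis=1)
        xs[k] = np.mean(0.5 * np.log(np.maximum(q, floor)))
        ys[k] = np.mean(np.log(np.maximum(l1, floor)))
    if alpha_grid.size == 2:
        return float(alpha_grid[-1])

    x1 = 0.5 * (xs[2:] - xs[:-2])
    y1 = 0.5 * (ys[2:] - ys[:-2])
    x2 = xs[2:] - 2.0 * xs[1:-1] + xs[:-2]
    y2 = ys[2:] - 2.0 * ys[1:-1] + ys[:-2]
    denom = np.power(x1 * x1 + y1 * y1, 1.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, (x1 * y2 - y1 * x2) / denom, -np.inf)
    # interior index of maximum curvature; prefer the larger alpha on ties
    rev = kappa[::-1]
    k_star = kappa.size - 1 - int(np.argmax(rev)) + 1
    return float(alpha_grid[k_star])


def estimate_pair(
    series: ExpressionTimeSeries, i: int, j: int, alpha: float
) -> tuple[float, float, float, float]:
    """Half-life estimates for both genes of a pair.

    Solves the backward system of (i, j) — yielding gene i's half-life —
    and the forward system (identically the backward system of (j, i)) for
    gene j's.  Returns ``(h_i, h_j, q_backward, q_forward)``; rank-deficient
    systems yield an undefined half-life with infinite fit error.
    """
    out_h = []
    out_q = []
    for a, bb in ((i, j), (j, i)):
        sys_ab = build_pair_system(series, a, bb, "backward")
        if sys_ab.rank_deficient:
            out_h.append(float("nan"))
            out_q.append(float("inf"))
            continue
        est = solve_l1_nnls(sys_ab.A, sys_ab.y, alpha)
        out_h.append(est.halflife)
        out_q.append(est.q)
    return out_h[0], out_h[1], out_q[0], out_q[1]
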