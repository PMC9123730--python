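"""Discrete linear systems for gene pairs sharing a promoter activity.

For a pair of genes (i, j) whose transcription rates are proportional,
P_i = gamma_i * u(t) and P_j = gamma_j * u(t), the unknown common promoter
u(t) can be eliminated between the two first-order kinetic equations.
Integrating the resulting relation over each sampling interval with the
trapezoidal rule yields, per interval delta,

    D_j = theta1 * D_i + theta2 * I_i - theta3 * I_j

where D is the interval difference of a profile, I its trapezoidal
integral, and theta = [gamma_j/gamma_i, (gamma_j/gamma_i)*k_i, k_j].  The
"backward" system of (i, j) estimates gene i's decay rate k_i through the
ratio theta1/theta2; the "forward" system is the same construction with the
roles of i and j exchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .timeseries import ExpressionTimeSeries

__all__ = [
    "PairSystem",
    "interval_differences",
    "trapezoid_integrals",
    "build_pair_system",
    "gram_tables",
]

#: Relative singular-value threshold below which a design matrix is flagged
#: rank-deficient (e.g. exactly proportional profiles).
RANK_TOL = 1e-10


def interval_differences(row, times=None) -> np.ndarray:
    """First differences D^delta = x(t_{delta+1}) - x(t_delta)."""
    row = np.asarray(row, dtype=float)
    if times is not None:
        times = np.asarray(times, dtype=float)
        if row.shape != times.shape:
            raise ValueError(
                f"profile length {row.size} does not match grid length {times.size}"
            )
    return np.diff(row)


def trapezoid_integrals(row, times) -> np.ndarray:
    """Per-interval trapezoidal integrals, valid on non-uniform grids.

    I^delta = (x(t_{delta+1}) + x(t_delta)) / 2 * (t_{delta+1} - t_delta).
    """
    row = np.asarray(row, dtype=float)
    times = np.asarray(times, dtype=float)
    if row.shape != times.shape:
        raise ValueError(
            f"profile length {row.size} does not match grid length {times.size}"
        )
    widths = np.diff(times)
    if np.any(widths <= 0):
        raise ValueError("times must be strictly increasing")
    return 0.5 * (row[1:] + row[:-1]) * widths


@dataclass(frozen=True)
class PairSystem:
    """One orientation of the discretized pair model for genes (i, j).

    ``A`` is the (T-1) x 3 design matrix, ``y`` the response vector.  For
    the backward orientation the columns are [D_i | I_i | -I_j] with
    y = D_j; the forward orientation of (i, j) is exactly the backward
    orientation of (j, i).
    """

    gene_i: int
    gene_j: int
    orientation: Literal["backward", "forward"]
    A: np.ndarray
    y: np.ndarray
    rank_deficient: bool = False


def build_pair_system(
    series: ExpressionTimeSeries,
    i: int,
    j: int,
    orientation: Literal["backward", "forward"] = "backward",
) -> PairSystem:
    """Assemble the backward or forward linear system for the pair (i, j).

    Rank deficiency (relative singular value below ``RANK_TOL``, e.g. for
    exactly proportional profiles) is flagged, not treated as an error; the
    downstream error filter removes such systems.
    """
    if i == j:
        raise ValueError("a pair system requires two distinct genes (i != j)")
    if orientation not in ("backward", "forward"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    a, b = (i, j) if orientation == "backward" else (j, i)
    # backward columns of the ordered pair (a, b): [D_a | I_a | -I_b], y = D_b
    x_a, x_b = series.values[a], series.values[b]
    D_a = interval_differences(x_a, series.times)
    D_b = interval_differences(x_b, series.times)
    I_a = trapezoid_integrals(x_a, series.times)
    I_b = trapezoid_integrals(x_b, series.times)
    A = np.column_stack([D_a, I_a, -I_b])
    sv = np.linalg.svd(A, compute_uv=False)
    deficient = bool(sv[-1] <= RANK_TOL * sv[0])
    return PairSystem(i, j, orientation, A, D_b.copy(), deficient)


def gram_tables(
    values: np.ndarray, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cross-product tables of per-gene difference and integral vectors.

    Returns (DD, DI, II) where DD[a, b] = D_a . D_b, DI[a, b] = D_a . I_b
    and II[a, b] = I_a . I_b.  Every pairwise normal-equation system is a
    small rearrangement of entries of these m x m tables, so they make the
    m(m-1) pairwise solves tractable: D and I are computed once per gene
    (O(mT)) and shared across all pairs.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    times = np.asarray(times, dtype=float)
    D = np.diff(values, axis=1)
    widths = np.diff(times)
    if np.any(widths <= 0):
        raise ValueError("times must be strictly increasing")
    I = 0.5 * (values[:, 1:] + values[:, :-1]) * widths
    return D @ D.T, D @ I.T, I @ I.T
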