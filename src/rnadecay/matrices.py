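"""Assembly of the pairwise half-life (H) and fit-error (Q) matrices.

Every ordered pair (i, j) of genes contributes one estimate of gene i's
half-life (the backward system of the pair; the forward system of (i, j)
is the backward system of (j, i)).  Estimates are stored at H[i, j] and
their squared-residual fit errors at Q[i, j]; the diagonals are zero.  Row
i of H thus holds the m-1 candidate estimates for gene i, to be filtered
by fit error and summarized by their median downstream.

The m(m-1) solves are performed in vectorized chunks on the normal
equations, whose ingredients are gathered from the per-gene Gram tables
(see :func:`rnadecay.pairsys.gram_tables`) rather than by materializing
each (T-1) x 3 design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .pairsys import RANK_TOL, gram_tables
from .solver import LN2, solve_gram_batch
from .timeseries import ExpressionTimeSeries

__all__ = ["HalfLifeMatrices", "build_matrices"]


@dataclass(frozen=True)
class HalfLifeMatrices:
    """m x m half-life estimates (H) and fit errors (Q), zero diagonal.

    Undefined half-lives are stored as NaN in H; rank-deficient systems
    carry an infinite fit error in Q so that any error threshold removes
    them.
    """

    gene_ids: tuple[str, ...]
    H: np.ndarray
    Q: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.H.shape[0]


def _assemble_gram(DD, DI, II, ii, jj):
    """Normal-equation ingredients of the backward systems of pairs (ii, jj).

    Columns of the design matrix are [D_i | I_i | -I_j], response D_j.
    """
    n = ii.size
    dDD, dII, dDI = np.diag(DD), np.diag(II), np.diag(DI)
    G = np.empty((n, 3, 3))
    G[:, 0, 0] = dDD[ii]
    G[:, 0, 1] = G[:, 1, 0] = dDI[ii]
    G[:, 0, 2] = G[:, 2, 0] = -DI[ii, jj]
    G[:, 1, 1] = dII[ii]
    G[:, 1, 2] = G[:, 2, 1] = -II[ii, jj]
    G[:, 2, 2] = dII[jj]
    b = np.empty((n, 3))
    b[:, 0] = DD[ii, jj]
    b[:, 1] = DI[jj, ii]
    b[:, 2] = -dDI[jj]
    yty = dDD[jj]
    return G, b, yty


def _solve_chunk(DD, DI, II, ii, jj, alpha):
    G, b, yty = _assemble_gram(DD, DI, II, ii, jj)
    # flag rank-deficient systems: smallest relative singular value of the
    # design matrix (eigenvalues of G are its squared singular values)
    eig = np.linalg.eigvalsh(G)
    sv_min = np.sqrt(np.maximum(eig[:, 0], 0.0))
    sv_max = np.sqrt(np.maximum(eig[:, -1], 0.0))
    deficient = sv_min <= RANK_TOL * sv_max
    theta, q, _ = solve_gram_batch(G, b, yty, alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(
            (theta[:, 0] > 0) & (theta[:, 1] > 0),
            LN2 * theta[:, 0] / theta[:, 1],
            np.nan,
        )
    h[deficient] = np.nan
    q[deficient] = np.inf
    return h, q


def build_matrices(
    series: ExpressionTimeSeries,
    alpha: float,
    n_jobs: int = 1,
    chunk_size: int = 200_000,
) -> HalfLifeMatrices:
    """Solve all m(m-1) pair systems and collect H and Q.

    Deterministic given its inputs; with ``n_jobs > 1`` chunks of pairs are
    solved in parallel threads, each writing a disjoint slice of the
    output, so results are identical for any worker count.
    """
    m = series.n_genes
    if m < 2:
        raise ValueError("need at least 2 genes to form a pair")
    if series.n_times < 2:
        raise ValueError("need at least 2 time points")
    DD, DI, II = gram_tables(series.values, series.times)
    off = ~np.eye(m, dtype=bool)
    ii, jj = np.nonzero(off)

    H = np.zeros((m, m))
    Q = np.zeros((m, m))
    chunks = [
        (ii[s : s + chunk_size], jj[s : s + chunk_size])
        for s in range(0, ii.size, chunk_size)
    ]
    if n_jobs == 1 or len(chunks) == 1:
        results = [_solve_chunk(DD, DI, II, ci, cj, alpha) for ci, cj in chunks]
    else:
        results = Parallel(n_jobs=n_jobs, prefer="threads")(
            delayed(_solve_chunk)(DD, DI, II, ci, cj, alpha) for ci, cj in chunks
        )
    for (ci, cj), (h, q) in zip(chunks, results):
        H[ci, cj] = h
        Q[ci, cj] = q
    return HalfLifeMatrices(series.gene_ids, H, Q)
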