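"""Error-threshold selection against a permutation null, and aggregation.

A pairwise estimate is only as good as its fit, so the H matrix is
filtered by a fit-error threshold q_max before per-gene aggregation.  The
threshold is chosen objectively against a permutation null: the whole
pairwise estimation is repeated on data whose time samples have been
shuffled independently per gene (destroying kinetics while preserving each
gene's value distribution), and q_max is the smallest percentile of the
fit-error distribution such that at least 90% of genes show a
significantly different (FDR < 0.05, Benjamini-Hochberg over genes)
distribution of surviving half-life estimates from their null
counterparts, per a two-sample Kolmogorov-Smirnov test.

Surviving row entries of H are then summarized by their median, one
half-life per gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrices import HalfLifeMatrices
from .timeseries import ExpressionTimeSeries

__all__ = [
    "FilterResult",
    "shuffle_dataset",
    "ks_two_sample",
    "bh_fdr",
    "select_qmax",
    "filter_and_median",
]

MIN_KS_SAMPLES = 3  # fewer surviving estimates than this cannot be validated


@dataclass
class FilterResult:
    """Outcome of the q_max selection.

    ``coverage_met`` is False when no percentile reaches the requested
    coverage and the 100th was returned as a fallback.  ``table`` (the
    per-gene half-life summary) is attached by the pipeline after
    filtering.
    """

    q_max_percentile: int
    q_max_value: float
    pvalues: np.ndarray
    fdr: np.ndarray
    pass_fraction: float
    coverage_met: bool = True
    table: pd.DataFrame | None = None


def shuffle_dataset(series: ExpressionTimeSeries, seed) -> ExpressionTimeSeries:
    """Independently permute each gene's values across time (seeded).

    The permutation preserves each row's value multiset — and hence its
    mean and standard deviation, so a normalized series stays normalized —
    while destroying its temporal structure.
    """
    rng = np.random.default_rng(seed)
    shuffled = np.empty_like(series.values)
    for g in range(series.n_genes):
        shuffled[g] = series.values[g, rng.permutation(series.n_times)]
    return ExpressionTimeSeries(
        series.gene_ids, series.times, shuffled, normalized=series.normalized
    )


def ks_two_sample(a, b, return_statistic: bool = False):
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    An empty sample yields p = 1 by convention: no evidence of a
    difference can be claimed from nothing.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        return (0.0, 1.0) if return_statistic else 1.0
    res = stats.ks_2samp(a, b, method="asymp")
    if return_statistic:
        return float(res.statistic), float(res.pvalue)
    return float(res.pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _row_survivors(hq: HalfLifeMatrices, q_threshold: float) -> list[np.ndarray]:
    """Per gene, the finite row estimates whose fit error is below threshold."""
    mask = (hq.Q < q_threshold) & np.isfinite(hq.H)
    np.fill_diagonal(mask, False)
    return [hq.H[g, mask[g]] for g in range(hq.n_genes)]


def _gene_pvalues(real_rows, null_rows) -> np.ndarray:
    p = np.ones(len(real_rows))
    for g, (a, b) in enumerate(zip(real_rows, null_rows)):
        if a.size >= MIN_KS_SAMPLES and b.size >= MIN_KS_SAMPLES:
            p[g] = ks_two_sample(a, b)
    return p


def select_qmax(
    hq_real: HalfLifeMatrices,
    hq_null: HalfLifeMatrices,
    fdr_threshold: float = 0.05,
    coverage: float = 0.90,
) -> FilterResult:
    """Smallest fit-error percentile at which >= ``coverage`` of genes pass.

    Candidate thresholds are the integer percentiles 1..100 of the pooled
    finite fit errors of the real data; the null (shuffled-data) matrix is
    thresholded at the same percentile of its own fit-error distribution,
    so that the per-gene comparison sees matched numbers of survivors on
    both sides at every candidate.  Per gene, a KS test compares its
    surviving real-row estimates with its surviving null-row estimates
    (genes with fewer than 3 survivors on either side get p = 1); BH
    adjustment runs across genes, and a gene passes at
    FDR < ``fdr_threshold``.  If no percentile reaches the coverage the
    100th is returned with ``coverage_met=False``.
    """
    if hq_real.n_genes != hq_null.n_genes:
        raise ValueError("real and null matrices must cover the same genes")
    off = ~np.eye(hq_real.n_genes, dtype=bool)
    pooled = hq_real.Q[off]
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise ValueError("no finite fit errors to build a threshold from")
    pooled_null = hq_null.Q[off]
    pooled_null = pooled_null[np.isfinite(pooled_null)]
    thresholds = np.percentile(pooled, np.arange(1, 101))
    thresholds_null = (
        np.percentile(pooled_null, np.arange(1, 101))
        if pooled_null.size
        else np.full(100, -np.inf)
    )

    fallback = None
    for c in range(1, 101):
        qc = float(thresholds[c - 1])
        p = _gene_pvalues(
            _row_survivors(hq_real, qc),
            _row_survivors(hq_null, float(thresholds_null[c - 1])),
        )
        fdr = bh_fdr(p)
        pass_fraction = float(np.mean(fdr < fdr_threshold))
        result = FilterResult(c, qc, p, fdr, pass_fraction)
        if pass_fraction >= coverage:
            return result
        fallback = result
    fallback.coverage_met = False
    return fallback


def filter_and_median(
    hq: HalfLifeMatrices | None = None,
    q_max_value: float | None = None,
    *,
    H: np.ndarray | None = None,
    Q: np.ndarray | None = None,
    gene_ids=None,
) -> pd.DataFrame:
    """Per-gene median of the row estimates surviving the error threshold.

    Entries with fit error >= ``q_max_value`` (or undefined estimates) are
    removed; each gene's half-life is the median of its surviving row
    entries (midpoint convention for even counts, as with any standard
    median), reported as NaN with survivor count 0 when nothing survives.
    """
    if hq is not None:
        H, Q, gene_ids = hq.H, hq.Q, hq.gene_ids
    if H is None or Q is None:
        raise ValueError("provide either a HalfLifeMatrices or H and Q arrays")
    if q_max_value is None or not np.isfinite(q_max_value):
        raise ValueError("q_max_value must be finite")
    m = H.shape[0]
    if gene_ids is None:
        gene_ids = [str(g) for g in range(m)]
    mask = (Q < q_max_value) & np.isfinite(H)
    np.fill_diagonal(mask, False)
    halflives = np.full(m, np.nan)
    counts = mask.sum(axis=1)
    for g in range(m):
        if counts[g]:
            halflives[g] = np.median(H[g, mask[g]])
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "halflife": halflives,
            "n_estimates": counts.astype(int),
        }
    )
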