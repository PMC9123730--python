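"""Expression time-series container and pre-processing.

The estimator consumes a genes x time-points matrix of RNA abundance
measurements sampled (possibly non-uniformly) in minutes.  Pre-processing
consists of per-gene z-scoring, an optional fold-ratio filter on raw
profiles, and an optional regularization of strongly non-uniform sampling
grids (merging intervals into the fewest trapezoids of comparable area, so
that the integral columns of the pairwise design matrices stay well
conditioned).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionTimeSeries",
    "zscore_normalize",
    "fold_ratio_filter",
    "regularize_sampling",
    "restrict_to_boundaries",
]

#: Minimum number of time points required by the pairwise estimator: T points
#: yield T-1 interval equations and the per-pair model has 3 unknowns, so the
#: systems are overdetermined only for T >= 5.
MIN_TIMEPOINTS_ESTIMATION = 5

_NORMALIZED_ATOL = 1e-9


@dataclass(frozen=True)
class ExpressionTimeSeries:
    """A genes x time-points expression matrix with its sampling grid.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row of ``values``.
    times
        Strictly increasing sampling times in minutes, length T >= 2.
    values
        m x T matrix of expression measurements.
    normalized
        True when every row has mean 0 and sample (ddof=1) s.d. 1.
    """

    gene_ids: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray
    normalized: bool = False

    def __init__(
        self,
        gene_ids: Sequence[str],
        times,
        values,
        normalized: bool = False,
    ) -> None:
        gene_ids = tuple(str(g) for g in gene_ids)
        times = np.asarray(times, dtype=float)
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if times.ndim != 1 or times.size < 2:
            raise ValueError("at least 2 sampling times are required")
        if np.any(np.diff(times) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if len(set(gene_ids)) != len(gene_ids):
            dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {', '.join(dupes)}")
        if values.shape != (len(gene_ids), times.size):
            raise ValueError(
                f"values has shape {values.shape}, expected "
                f"({len(gene_ids)}, {times.size})"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite (no missing entries)")
        if normalized:
            mu = values.mean(axis=1)
            sd = values.std(axis=1, ddof=1)
            if not (
                np.allclose(mu, 0.0, atol=_NORMALIZED_ATOL)
                and np.allclose(sd, 1.0, atol=_NORMALIZED_ATOL)
            ):
                raise ValueError(
                    "normalized=True but rows are not zero-mean / unit-sd"
                )
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "normalized", normalized)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def subset(self, indices: Sequence[int]) -> "ExpressionTimeSeries":
        """Return a copy restricted to the given gene rows (order kept)."""
        idx = list(indices)
        return ExpressionTimeSeries(
            [self.gene_ids[i] for i in idx],
            self.times,
            self.values[idx],
            normalized=self.normalized,
        )


def zscore_normalize(series: ExpressionTimeSeries) -> ExpressionTimeSeries:
    """Z-score every gene profile to zero mean and unit sample s.d.

    A constant profile carries no kinetic information (its level is set by
    the ratio of production to degradation, not by the decay rate alone) and
    has zero standard deviation, so it is rejected.
    """
    values = series.values
    sd = values.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(series.gene_ids[i] for i in bad[:5])
        raise ValueError(
            f"constant profile (zero standard deviation) for gene(s): {names}"
        )
    normed = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return ExpressionTimeSeries(
        series.gene_ids, series.times, normed, normalized=True
    )


def fold_ratio_filter(
    series: ExpressionTimeSeries, threshold: float
) -> ExpressionTimeSeries:
    """Keep genes whose max/min raw expression ratio exceeds ``threshold``.

    Genes with a small dynamic range over the time course provide little
    leverage on kinetics; this optional filter removes them.  Operates on
    raw (strictly positive) values only: z-scored profiles have negative
    entries and an undefined fold ratio.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if series.normalized:
        raise ValueError("fold_ratio_filter requires raw (non-normalized) data")
    if np.any(series.values <= 0):
        raise ValueError(
            "fold ratio undefined: expression values must be strictly positive"
        )
    ratios = series.values.max(axis=1) / series.values.min(axis=1)
    keep = np.flatnonzero(ratios > threshold)
    return series.subset(keep)


def _interval_cv(times: np.ndarray) -> float:
    widths = np.diff(times)
    return float(widths.std(ddof=1) / widths.mean()) if widths.size > 1 else 0.0


def _segment_areas(signal: np.ndarray, times: np.ndarray, bounds: list[int]) -> np.ndarray:
    """Endpoint-trapezoid area of the mean |signal| for each segment."""
    b = np.asarray(bounds)
    left, right = b[:-1], b[1:]
    return 0.5 * (signal[left] + signal[right]) * (times[right] - times[left])


def regularize_sampling(
    times,
    values,
    tau: float = 10.0,
    cv_threshold: float = 0.1,
    min_segments: int = 4,
) -> np.ndarray:
    """Partition a non-uniform grid into few trapezoids of comparable area.

    Strongly non-uniform sampling makes the integral entries of the pair
    design matrices span orders of magnitude, which degrades their
    conditioning.  This routine greedily merges adjacent intervals until the
    max/min ratio of segment areas (endpoint trapezoids of the dataset-mean
    absolute signal) is at most ``tau``, returning segment boundaries as
    indices into ``times`` (first and last always included).

    Grids whose interval lengths have a coefficient of variation below
    ``cv_threshold`` are considered effectively uniform and returned
    unchanged.  Merging never goes below ``min_segments`` segments when the
    input has more than that (the downstream pair systems need more rows
    than their 3 unknowns); shorter grids may merge down to 2 segments.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("at least 2 time points are required")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    all_bounds = np.arange(times.size)
    if _interval_cv(times) < cv_threshold:
        return all_bounds

    signal = np.mean(np.abs(np.atleast_2d(np.asarray(values, dtype=float))), axis=0)
    n_segments = times.size - 1
    floor = min_segments if n_segments > min_segments else 2
    bounds = list(range(times.size))

    def ratio(b: list[int]) -> float:
        areas = _segment_areas(signal, times, b)
        lo = areas.min()
        return np.inf if lo <= 0 else float(areas.max() / lo)

    while len(bounds) - 1 > floor and ratio(bounds) > tau:
        # drop the interior boundary whose removal best reduces the area ratio
        candidates = [
            (ratio(bounds[:k] + bounds[k + 1 :]), k)
            for k in range(1, len(bounds) - 1)
        ]
        _, best_k = min(candidates, key=lambda rk: (rk[0], rk[1]))
        del bounds[best_k]
    return np.asarray(bounds)


def restrict_to_boundaries(
    series: ExpressionTimeSeries, boundaries: np.ndarray
) -> ExpressionTimeSeries:
    """Restrict a series to the time points selected by ``regularize_sampling``.

    The restricted rows are no longer exactly zero-mean / unit-sd, so the
    result is returned with ``normalized=False``; callers should re-apply
    :func:`zscore_normalize`.
    """
    boundaries = np.asarray(boundaries)
    return ExpressionTimeSeries(
        series.gene_ids,
        series.times[boundaries],
        series.values[:, boundaries],
        normalized=False,
    )
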