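"""Reading expression matrices and writing result tables.

The input format is a delimited text matrix (tab or comma, auto-detected):
first column gene identifiers, header row of numeric sampling times in
minutes.  Half-life outputs are reported in the units of the time header
and never rescaled silently.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .filtering import FilterResult
from .matrices import HalfLifeMatrices
from .timeseries import ExpressionTimeSeries

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "write_results",
]


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_expression_matrix(path) -> ExpressionTimeSeries:
    """Parse a genes x times matrix into an :class:`ExpressionTimeSeries`."""
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, header=0, dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected a gene-id column plus >= 2 time columns")
    try:
        times = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(
            f"{path}: header must contain numeric sampling times ({exc})"
        ) from None
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: sampling times in the header must be strictly increasing")
    gene_ids = df.iloc[:, 0].tolist()
    dupes = df.iloc[:, 0][df.iloc[:, 0].duplicated()].unique()
    if dupes.size:
        raise ValueError(f"{path}: duplicate gene id(s): {', '.join(map(str, dupes))}")
    values = df.iloc[:, 1:].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for col in df.columns[1:]:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise ValueError(
                    f"{path}: non-numeric value {df.loc[row, col]!r} at "
                    f"gene {gene_ids[row]!r}, time column {col!r}"
                )
        values = df.iloc[:, 1:].astype(float).to_numpy()
    if np.isnan(values).any():
        ii, jj = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path}: missing value at gene {gene_ids[ii]!r}, "
            f"time column {df.columns[1 + jj]!r}"
        )
    return ExpressionTimeSeries(gene_ids, times, values)


def write_expression_matrix(series: ExpressionTimeSeries, path, sep: str = "\t") -> None:
    df = pd.DataFrame(series.values, columns=[repr(float(t)) for t in series.times])
    df.insert(0, "gene", list(series.gene_ids))
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def write_results(
    table: pd.DataFrame,
    filter_result: FilterResult,
    config: dict,
    outdir,
    matrices: HalfLifeMatrices | None = None,
) -> dict[str, Path]:
    """Write the per-gene table, run metadata and (optionally) H/Q dumps.

    Returns a mapping of artifact name to path.  The per-gene table keeps
    12 significant digits so that values round-trip; the metadata record
    is plain ``key=value`` text including every tunable and the seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    out = table.copy()
    out["fdr"] = filter_result.fdr
    table_path = outdir / "halflives.tsv"
    out.to_csv(table_path, sep="\t", index=False, float_format="%.12g")
    written["table"] = table_path

    meta = dict(config)
    meta.update(
        q_max_percentile=filter_result.q_max_percentile,
        q_max_value=repr(filter_result.q_max_value),
        pass_fraction=repr(filter_result.pass_fraction),
        coverage_met=filter_result.coverage_met,
    )
    meta_path = outdir / "run_metadata.txt"
    with open(meta_path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"{key}={value}\n")
    written["metadata"] = meta_path

    if matrices is not None:
        for name, mat in (("H", matrices.H), ("Q", matrices.Q)):
            p = outdir / f"{name}.tsv"
            pd.DataFrame(mat, index=list(matrices.gene_ids)).to_csv(
                p, sep="\t", header=False, float_format="%.12g"
            )
            written[name] = p
    return written
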