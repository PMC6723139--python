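"""Sorted-group descriptive check for a scale effect in real trait records.

If a trait's variability follows a constant-CV scale effect, then within
groups of records of similar magnitude the standard deviation should grow
proportionally with the group mean, leaving the within-group CV roughly
constant.  Sorting the records and summarising equal-count quantile bins
(mean, SD, CV per bin) makes that pattern visible: a flat CV profile is
consistent with a full-strength scale effect, a declining CV suggests the
mean-variability link is only partial.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["BinSummary", "quantile_bin_summary", "bin_summary_frame", "load_trait_column"]


@dataclass(frozen=True)
class BinSummary:
    """Descriptive statistics of one rank group (1-based index)."""

    bin_index: int
    n: int
    mean: float
    sd: float
    cv: float


def quantile_bin_summary(values, n_bins: int = 5) -> list[BinSummary]:
    """Mean, SD and CV within equal-count bins of the sorted values.

    Records are sorted ascending (stable, so ties keep input order and are
    split by position) and divided into ``n_bins`` contiguous groups of
    near-equal size; when the count is not divisible the lowest-index bins
    take one extra record.  SD uses the n - 1 denominator; cv = sd / mean.
    """
    values = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if values.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must all be finite")
    if values.size < 2 * n_bins:
        raise ValueError(
            f"need at least {2 * n_bins} records for {n_bins} bins, got {values.size}"
        )
    ordered = values[np.argsort(values, kind="stable")]
    groups = np.array_split(ordered, n_bins)
    out = []
    for i, g in enumerate(groups, start=1):
        mean = float(g.mean())
        if mean == 0.0:
            raise ValueError(f"bin {i} has mean exactly 0: cv undefined")
        sd = float(np.std(g, ddof=1))
        out.append(BinSummary(bin_index=i, n=int(g.size), mean=mean, sd=sd, cv=sd / mean))
    return out


def bin_summary_frame(values, n_bins: int = 5) -> pd.DataFrame:
    """Same as :func:`quantile_bin_summary`, as a DataFrame."""
    return pd.DataFrame([vars(b) for b in quantile_bin_summary(values, n_bins)])


def load_trait_column(
    path: str | Path,
    column: str | int | None = None,
    *,
    has_header: bool = True,
) -> np.ndarray:
    """Read one numeric column of trait records from a CSV file.

    ``column`` may be a header name, a 0-based position, or None for the
    first column.  Raises ValueError naming the available columns when the
    requested one does not exist.
    """
    df = pd.read_csv(path, header=0 if has_header else None)
    if column is None:
        col = df.columns[0]
    elif isinstance(column, int) or (isinstance(column, str) and column.isdigit()):
        idx = int(column)
        if idx >= df.shape[1]:
            raise ValueError(
                f"column index {idx} out of range; file has {df.shape[1]} columns: "
                f"{list(df.columns)}"
            )
        col = df.columns[idx]
    else:
        if column not in df.columns:
            raise ValueError(
                f"column {column!r} not found; available columns: {list(df.columns)}"
            )
        col = column
    values = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
    return values
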