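"""Normality screening, class-median imputation and median/IQR descriptives.

All quantiles in this package use linear interpolation between order
statistics (``numpy``'s default), one convention applied everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class MarkerSummary:
    marker_name: str
    group_id: object
    n: int
    median: float
    q25: float
    q75: float


def ks_normality_screen(values, alpha: float = 0.05) -> tuple[float, float, bool]:
    """One-sample Kolmogorov-Smirnov screen against a fitted normal.

    Tests the values against a normal distribution with mean and SD
    estimated from the sample itself (no small-sample correction is
    applied, so the screen is conservative).  Returns ``(statistic,
    p_value, non_normal)`` with ``non_normal = (p <= alpha)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for a normality screen")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant input: degenerate distribution has no normal fit")
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat), float(p), bool(p <= alpha)


def impute_class_median(table: pd.DataFrame, marker: str, class_column: str) -> pd.DataFrame:
    """Fill missing marker values with the median of their own class.

    Observed values are untouched; each class's observed median is
    therefore unchanged by the operation, which is also idempotent.
    Raises if any class has no observed value to take a median from.
    """
    if marker not in table.columns:
        raise KeyError(f"unknown marker column {marker!r}")
    if class_column not in table.columns:
        raise KeyError(f"unknown class column {class_column!r}")
    out = table.copy()
    for cls, sub in out.groupby(class_column, sort=True):
        observed = sub[marker].dropna()
        n_missing = sub[marker].isna().sum()
        if n_missing == 0:
            continue
        if observed.empty:
            raise ValueError(
                f"cannot impute marker {marker!r}: class {cls!r} has no observed values"
            )
        fill = float(observed.median())
        idx = sub.index[sub[marker].isna()]
        out.loc[idx, marker] = fill
    return out


def impute_markers(table: pd.DataFrame, markers, class_column: str) -> pd.DataFrame:
    """Apply :func:`impute_class_median` to each marker in an allow-list."""
    out = table
    for m in markers:
        out = impute_class_median(out, m, class_column)
    return out


def describe(values, group_labels, marker_name: str = "") -> list[MarkerSummary]:
    """Per-group n/median/q25/q75 using linear-interpolation quantiles.

    Groups appear in sorted label order; empty groups are skipped with a
    warning.  NaNs within a group are dropped before summarising.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    if values.shape != group_labels.shape:
        raise ValueError("values and group_labels must have the same length")
    out: list[MarkerSummary] = []
    for g in sorted(pd.unique(group_labels)):
        x = values[group_labels == g]
        x = x[np.isfinite(x)]
        if x.size == 0:
            warnings.warn(f"group {g!r} has no observed values; skipped", stacklevel=2)
            continue
        out.append(
            MarkerSummary(
                marker_name=marker_name,
                group_id=g,
                n=int(x.size),
                median=float(np.median(x)),
                q25=float(np.percentile(x, 25)),
                q75=float(np.percentile(x, 75)),
            )
        )
    return out


def summarise_markers(table: pd.DataFrame, markers, group_column: str) -> pd.DataFrame:
    """Tidy summary frame (marker, group, n, median, q25, q75) for many markers."""
    rows = []
    for m in markers:
        for s in describe(table[m].to_numpy(), table[group_column].to_numpy(), m):
            rows.append(
                {"marker": s.marker_name, "group": s.group_id, "n": s.n,
                 "median": s.median, "q25": s.q25, "q75": s.q75}
            )
    return pd.DataFrame(rows)
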