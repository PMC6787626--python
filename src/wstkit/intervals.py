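"""Median/IQR reference intervals per marker and group, with overlap checks.

"Reference interval" here means the (q25, q75) band around the median as
used for between-group comparison — deliberately narrower than the
clinical-chemistry 2.5-97.5% convention.  Do not read these bands as
population reference ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ReferenceInterval:
    marker: str
    group_id: object
    n: int
    median: float
    q25: float
    q75: float
    correct_only: bool = False

    def __post_init__(self):
        if not (self.q25 <= self.median <= self.q75):
            raise ValueError(
                f"{self.marker}/{self.group_id}: need q25 <= median <= q75"
            )


@dataclass(frozen=True)
class OverlapReport:
    marker: str
    group_pair: tuple
    overlap: bool
    width: float  # overlap length (>= 0) or signed gap (< 0)


def class_reference_intervals(
    table: pd.DataFrame,
    markers,
    group_column: str,
    correct_mask=None,
) -> list[ReferenceInterval]:
    """One (median, q25, q75) interval per marker per group.

    ``correct_mask`` (boolean, row-aligned) restricts to correctly
    predicted cases first; a group emptied by the mask raises.  Quantiles
    use the repo-wide linear-interpolation convention.
    """
    work = table
    correct_only = correct_mask is not None
    if correct_only:
        mask = np.asarray(correct_mask, dtype=bool)
        if mask.shape[0] != len(table):
            raise ValueError("correct_mask is not row-aligned with the table")
        before = set(table[group_column].dropna().unique())
        work = table.loc[mask]
        after = set(work[group_column].dropna().unique())
        gone = [g.item() if hasattr(g, "item") else g for g in sorted(before - after)]
        if gone:
            raise ValueError(f"group(s) emptied by the correct-prediction mask: {gone}")
    out: list[ReferenceInterval] = []
    for marker in markers:
        if marker not in work.columns:
            raise KeyError(f"unknown marker column {marker!r}")
        for g, sub in work.groupby(group_column, sort=True):
            x = sub[marker].dropna().to_numpy(dtype=float)
            if x.size == 0:
                raise ValueError(f"group {g!r} has no observed {marker!r} values")
            out.append(
                ReferenceInterval(
                    marker=marker,
                    group_id=g,
                    n=int(x.size),
                    median=float(np.median(x)),
                    q25=float(np.percentile(x, 25)),
                    q75=float(np.percentile(x, 75)),
                    correct_only=correct_only,
                )
            )
    return out


def interval_overlap(a: ReferenceInterval, b: ReferenceInterval) -> OverlapReport:
    """Closed-interval overlap of two IQR bands for the same marker.

    Touching endpoints count as overlap.  ``width`` is the overlap length
    when positive, or the (negative) gap between the bands when they are
    disjoint.
    """
    if a.marker != b.marker:
        raise ValueError(f"marker mismatch: {a.marker!r} vs {b.marker!r}")
    width = min(a.q75, b.q75) - max(a.q25, b.q25)
    return OverlapReport(
        marker=a.marker,
        group_pair=(a.group_id, b.group_id),
        overlap=bool(width >= 0),
        width=float(width),
    )


def intervals_frame(intervals: list[ReferenceInterval]) -> pd.DataFrame:
    """Tidy frame (marker, group, n, median, q25, q75, correct_only)."""
    return pd.DataFrame(
        [
            {"marker": iv.marker, "group": iv.group_id, "n": iv.n,
             "median": iv.median, "q25": iv.q25, "q75": iv.q75,
             "correct_only": iv.correct_only}
            for iv in intervals
        ]
    )


def overlap_matrix(intervals: list[ReferenceInterval], marker: str) -> pd.DataFrame:
    """Square overlap-width matrix between all groups for one marker."""
    ivs = [iv for iv in intervals if iv.marker == marker]
    groups = [iv.group_id for iv in ivs]
    mat = pd.DataFrame(index=groups, columns=groups, dtype=float)
    for x in ivs:
        for y in ivs:
            mat.loc[x.group_id, y.group_id] = interval_overlap(x, y).width
    return mat
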