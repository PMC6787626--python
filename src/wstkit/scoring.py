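"""Standing-test scoring.

The orthostatic-intolerance protocol records how long a participant can
remain upright (0-20 minutes, on a 2-minute grid) together with a subjective
standing-difficulty score.  Participants completing the full 20 minutes
report difficulty on a 0-10 ordinal scale; participants stopping early
receive a fixed code instead: 14 if they could not stand 10 minutes, 12 if
they stood at least 10 but under 20 minutes.

The weighted standing time (WST) down-weights standing time by difficulty::

    WST = standing_time * (1 - difficulty / 14)

and is the basis of a 4-class severity label (0 healthy control, 1 mild,
2 moderate, 3 severe) and a merged 3-class label (healthy+mild, moderate,
severe) used by the downstream model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: Standing time is recorded every 2 minutes, 0 through 20.
TIME_GRID = frozenset(range(0, 21, 2))

#: Valid difficulty values: the 0-10 ordinal scale plus early-stop codes.
VALID_DIFFICULTY = frozenset(range(0, 11)) | {12, 14}

#: Difficulty code for participants unable to stand 10 minutes.
CODE_UNDER_10_MIN = 14
#: Difficulty code for participants standing >=10 but <20 minutes.
CODE_10_TO_20_MIN = 12

#: Diagnosis labels used throughout the cohort table.
HEALTHY = "HC"
CASE = "ME/CFS"


def _check_time(standing_time) -> int:
    t = float(standing_time)
    if not t.is_integer() or int(t) not in TIME_GRID:
        raise ValueError(
            f"standing_time must lie on the 2-minute grid 0-20, got {standing_time!r}"
        )
    return int(t)


def _check_difficulty(difficulty) -> int:
    d = float(difficulty)
    if not d.is_integer() or int(d) not in VALID_DIFFICULTY:
        raise ValueError(
            f"difficulty must be an integer in 0-10, 12 or 14, got {difficulty!r}"
        )
    return int(d)


def weighted_standing_time(standing_time, difficulty, ndigits: int | None = 2) -> float:
    """Weighted standing time: ``standing_time * (1 - difficulty/14)``.

    Parameters
    ----------
    standing_time : int
        Minutes upright, on the 2-minute grid 0-20.
    difficulty : int
        Standing difficulty: 0-10, or early-stop code 12 or 14.
    ndigits : int or None
        Decimal places for the reported value (default 2, matching how the
        scale is usually printed).  ``None`` returns the raw product;
        classification always works from raw time/difficulty, never from
        the rounded WST.
    """
    t = _check_time(standing_time)
    d = _check_difficulty(difficulty)
    w = t * (1.0 - d / 14.0)
    return w if ndigits is None else round(w, ndigits)


def assign_difficulty_code(standing_time, reported_difficulty=None) -> int:
    """Resolve the difficulty code from standing time and the reported score.

    Early stops override the self-reported scale: < 10 minutes scores 14,
    10-18 minutes scores 12.  Only participants standing the full 20 minutes
    keep their reported 0-10 difficulty, which is then required.
    """
    t = _check_time(standing_time)
    if t < 10:
        return CODE_UNDER_10_MIN
    if t < 20:
        return CODE_10_TO_20_MIN
    if reported_difficulty is None or (
        isinstance(reported_difficulty, float) and np.isnan(reported_difficulty)
    ):
        raise ValueError(
            "reported_difficulty is required when standing_time is 20 minutes"
        )
    d = _check_difficulty(reported_difficulty)
    if d > 10:
        raise ValueError(
            f"reported difficulty must be on the 0-10 scale for a full 20-minute "
            f"stand, got code {d}"
        )
    return d


def detect_pots(hr_supine, hr_standing_max) -> bool:
    """Postural orthostatic tachycardia: HR rise on standing >= 30 bpm."""
    if hr_supine <= 0 or hr_standing_max <= 0:
        raise ValueError("heart rates must be positive")
    return bool(hr_standing_max - hr_supine >= 30)


def classify_severity(diagnosis: str, standing_time, difficulty_code) -> int:
    """4-class severity from diagnosis and the resolved standing test.

    Healthy controls are class 0 regardless of the standing result (a
    control with an early-stop code is a protocol anomaly and triggers a
    warning, but stays class 0).  Cases standing the full 20 minutes are
    mild (class 1) at difficulty <= 3 and moderate (class 2) at 4-10;
    any early stop (code 12 or 14) is severe (class 3).
    """
    t = _check_time(standing_time)
    d = _check_difficulty(difficulty_code)
    if diagnosis == HEALTHY:
        if d in (CODE_10_TO_20_MIN, CODE_UNDER_10_MIN):
            warnings.warn(
                f"healthy control with early-stop difficulty code {d}; "
                "protocol anomaly, class 0 retained",
                stacklevel=2,
            )
        return 0
    if diagnosis != CASE:
        raise ValueError(f"diagnosis must be {HEALTHY!r} or {CASE!r}, got {diagnosis!r}")
    if d in (CODE_10_TO_20_MIN, CODE_UNDER_10_MIN):
        return 3
    if t != 20:
        raise ValueError(
            f"case with standing_time {t} < 20 must carry code 12 or 14, got {d}"
        )
    return 1 if d <= 3 else 2


def merge_classes(class4: int) -> int:
    """Merge the 4-class label to 3 classes: {0,1} -> 0, 2 -> 1, 3 -> 2."""
    if class4 not in (0, 1, 2, 3):
        raise ValueError(f"class4 must be in 0-3, got {class4!r}")
    return {0: 0, 1: 0, 2: 1, 3: 2}[class4]


def theoretical_wst_ranges() -> dict[int, tuple[float, float]]:
    """Min/max rounded WST attainable within each 4-class definition.

    Enumerates every (time, difficulty) pair admitted by a class and
    reports the extreme weighted standing times rounded to 2 decimals.
    Note the moderate class's theoretical minimum (5.71, at difficulty 10)
    is below the 6.43 sometimes quoted for observed cohorts.
    """
    pairs = {
        0: [(20, d) for d in range(1, 5)],
        1: [(20, d) for d in range(1, 4)],
        2: [(20, d) for d in range(4, 11)],
        3: [(t, CODE_UNDER_10_MIN if t < 10 else CODE_10_TO_20_MIN)
            for t in range(0, 20, 2)],
    }
    out = {}
    for cls, pts in pairs.items():
        vals = [weighted_standing_time(t, d) for t, d in pts]
        out[cls] = (min(vals), max(vals))
    return out


def score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``wst``, ``class4``, ``class3`` and ``pots`` columns to a cohort.

    Expects columns ``diagnosis``, ``standing_time``, ``difficulty``,
    ``hr_supine`` and ``hr_standing_max``.  ``difficulty`` may hold the
    reported 0-10 score or an already-resolved code; it is normalised via
    :func:`assign_difficulty_code` first.
    """
    required = ["diagnosis", "standing_time", "difficulty", "hr_supine", "hr_standing_max"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    out = table.copy()
    codes, wst, c4, c3, pots = [], [], [], [], []
    for row in table.itertuples(index=False):
        t = int(row.standing_time)
        code = assign_difficulty_code(t, row.difficulty if t == 20 else None)
        codes.append(code)
        wst.append(weighted_standing_time(t, code))
        cls = classify_severity(row.diagnosis, t, code)
        c4.append(cls)
        c3.append(merge_classes(cls))
        pots.append(detect_pots(row.hr_supine, row.hr_standing_max))
    out["difficulty"] = codes
    out["wst"] = wst
    out["class4"] = c4
    out["class3"] = c3
    out["pots"] = pots
    return out
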