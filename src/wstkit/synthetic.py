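"""Seeded synthetic-cohort generation.

Generates participant tables with the class structure, per-class marker
marginals and missingness pattern the downstream analysis assumes.  Marker
marginals are log-normal, fitted so the distribution median equals the
target median exactly and the quartile *ratio* q75/q25 is matched exactly
(individual quartiles are matched only when the target triple is
log-symmetric).  Markers are generated independently within class: no
within-class correlation structure is imposed, a documented limitation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from wstkit import defaults, scoring

#: Standard-normal 75th-percentile deviate used by the quantile fit.
Z75 = float(norm.ppf(0.75))


@dataclass(frozen=True)
class ClassMarkerSpec:
    """Target (median, q25, q75) for one marker in one severity class."""

    marker_name: str
    class_id: int
    median: float
    q25: float
    q75: float

    def __post_init__(self):
        if not (0 < self.q25 <= self.median <= self.q75):
            raise ValueError(
                f"{self.marker_name} class {self.class_id}: quantiles must satisfy "
                f"0 < q25 <= median <= q75, got "
                f"({self.median}, {self.q25}, {self.q75})"
            )


def fit_lognormal_from_quantiles(median: float, q25: float, q75: float) -> tuple[float, float]:
    """Log-normal (log_location, log_scale) matching a (median, q25, q75) triple.

    ``log_location = ln(median)`` and ``log_scale = ln(q75/q25) / (2 z)``
    with ``z`` the standard-normal 75th-percentile deviate.  The implied
    distribution's median equals ``median`` exactly and its quartile ratio
    equals ``q75/q25`` exactly.  A zero-spread triple yields a point mass
    (log_scale 0).
    """
    if not (0 < q25 <= median <= q75):
        raise ValueError(
            f"quantiles must satisfy 0 < q25 <= median <= q75, got "
            f"({median}, {q25}, {q75})"
        )
    return math.log(median), math.log(q75 / q25) / (2.0 * Z75)


# (min_difficulty, max_difficulty) drawn uniformly for full-20-minute classes.
_DEFAULT_DIFFICULTY_RANGES: dict[int, tuple[int, int]] = {
    0: (1, 4),
    1: (1, 3),
    2: (4, 10),
}


def _default_pots_rates() -> dict[int, float]:
    # controls have no postural tachycardia by default; case rates are
    # arbitrary plumbing values (no target prevalence is specified anywhere)
    return {0: 0.0, 1: 0.3, 2: 0.3, 3: 0.3}


@dataclass
class CohortConfig:
    """Full parameterisation of one synthetic cohort."""

    class_sizes: dict[int, int]
    marker_specs: list[ClassMarkerSpec]
    urine_missing_rate: float = 0.175
    seed: int = 0
    difficulty_ranges: dict[int, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_DIFFICULTY_RANGES)
    )
    pots_rates: dict[int, float] = field(default_factory=_default_pots_rates)
    missing_markers: tuple[str, ...] = defaults.URINE_MARKERS

    def __post_init__(self):
        for cls, n in self.class_sizes.items():
            if n < 0:
                raise ValueError(f"class {cls} size must be non-negative, got {n}")
        if not (0 <= self.urine_missing_rate < 1):
            raise ValueError("urine_missing_rate must lie in [0, 1)")
        for cls, (lo, hi) in self.difficulty_ranges.items():
            if not (0 <= lo <= hi <= 10):
                raise ValueError(
                    f"difficulty range for class {cls} must sit inside 0-10, got ({lo}, {hi})"
                )

    def spec_for(self, marker: str, class_id: int) -> ClassMarkerSpec:
        for s in self.marker_specs:
            if s.marker_name == marker and s.class_id == class_id:
                return s
        raise KeyError(f"no marker spec for ({marker!r}, class {class_id})")

    @property
    def marker_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.marker_specs:
            if s.marker_name not in seen:
                seen.append(s.marker_name)
        return seen

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        specs = [
            ClassMarkerSpec(
                marker_name=s["marker_name"],
                class_id=int(s["class_id"]),
                median=float(s["median"]),
                q25=float(s["q25"]),
                q75=float(s["q75"]),
            )
            for s in raw["marker_specs"]
        ]
        kwargs = dict(
            class_sizes={int(k): int(v) for k, v in raw["class_sizes"].items()},
            marker_specs=specs,
        )
        for key in ("urine_missing_rate", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "difficulty_ranges" in raw:
            kwargs["difficulty_ranges"] = {
                int(k): (int(v[0]), int(v[1])) for k, v in raw["difficulty_ranges"].items()
            }
        if "pots_rates" in raw:
            kwargs["pots_rates"] = {int(k): float(v) for k, v in raw["pots_rates"].items()}
        if "missing_markers" in raw:
            kwargs["missing_markers"] = tuple(raw["missing_markers"])
        return cls(**kwargs)


def default_cohort_config(seed: int = 0, class_sizes: dict[int, int] | None = None) -> CohortConfig:
    """Config reproducing the bundled per-class marker summaries.

    Class sizes default to the canonical 17/19/38/23 split (97 rows).
    """
    specs = [
        ClassMarkerSpec(marker, cls, *triple)
        for marker, by_class in defaults.MARKER_SUMMARIES_4CLASS.items()
        for cls, triple in by_class.items()
    ]
    return CohortConfig(
        class_sizes=dict(class_sizes or defaults.CLASS_SIZES_4CLASS),
        marker_specs=specs,
        seed=seed,
    )


def _draw_standing_test(cls: int, n: int, ranges: dict[int, tuple[int, int]], rng) -> tuple[np.ndarray, np.ndarray]:
    """(standing_time, difficulty) arrays consistent with the class definition."""
    if cls == 3:
        time = 2 * rng.integers(0, 10, size=n)  # 0..18 minutes
        diff = np.where(time < 10, scoring.CODE_UNDER_10_MIN, scoring.CODE_10_TO_20_MIN)
        return time, diff
    lo, hi = ranges[cls]
    return np.full(n, 20), rng.integers(lo, hi + 1, size=n)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one participant table from ``config`` (deterministic in seed).

    One row per participant: ``participant_id``, ``diagnosis`` (class 0 is
    healthy control, all others are cases), a (standing_time, difficulty)
    pair drawn from the class definition, supine/standing heart rates, and
    one independent log-normal draw per marker.  Missingness is injected
    into ``config.missing_markers`` at ``config.urine_missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    markers = config.marker_names
    frames = []
    for cls in sorted(config.class_sizes):
        n = config.class_sizes[cls]
        if n == 0:
            continue
        time, diff = _draw_standing_test(cls, n, config.difficulty_ranges, rng)
        hr_supine = np.round(rng.normal(68.0, 7.0, size=n)).clip(45, 110)
        pots = rng.random(n) < config.pots_rates.get(cls, 0.0)
        delta = np.where(pots, rng.uniform(30, 55, size=n), rng.uniform(2, 29, size=n))
        hr_standing = np.round(hr_supine + delta)
        cols = {
            "diagnosis": [scoring.HEALTHY if cls == 0 else scoring.CASE] * n,
            "standing_time": time.astype(int),
            "difficulty": diff.astype(int),
            "hr_supine": hr_supine.astype(int),
            "hr_standing_max": hr_standing.astype(int),
        }
        for marker in markers:
            spec = config.spec_for(marker, cls)
            mu, sigma = fit_lognormal_from_quantiles(spec.median, spec.q25, spec.q75)
            cols[marker] = np.exp(mu + sigma * rng.standard_normal(n))
        frames.append(pd.DataFrame(cols))
    if not frames:
        table = pd.DataFrame(
            columns=["diagnosis", "standing_time", "difficulty", "hr_supine",
                     "hr_standing_max", *markers]
        )
    else:
        table = pd.concat(frames, ignore_index=True)
    table.insert(0, "participant_id", [f"P{i:04d}" for i in range(len(table))])
    if config.urine_missing_rate > 0:
        present = [m for m in config.missing_markers if m in table.columns]
        table = inject_missingness(
            table, present, config.urine_missing_rate, seed=rng.integers(2**31)
        )
    return table


def inject_missingness(table: pd.DataFrame, markers, rate: float, seed) -> pd.DataFrame:
    """Independently blank each listed marker value with probability ``rate``."""
    if not (0 <= rate < 1):
        raise ValueError("rate must lie in [0, 1)")
    unknown = [m for m in markers if m not in table.columns]
    if unknown:
        raise KeyError(f"unknown marker column(s): {unknown}")
    out = table.copy()
    rng = np.random.default_rng(seed)
    for m in markers:
        mask = rng.random(len(out)) < rate
        out.loc[mask, m] = np.nan
    return out
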