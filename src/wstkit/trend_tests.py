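"""Nonparametric test battery: Mann-Whitney U, Kruskal-Wallis, Jonckheere-Terpstra.

The Jonckheere-Terpstra trend test is implemented from scratch: the
statistic J sums, over every ordered pair of groups (i < j), the number of
cross-group value pairs with the group-j value larger, counting ties as
one half.  Small samples (total n <= 12) get an exact permutation p-value
by full enumeration of group assignments; otherwise a tie-corrected normal
approximation is used.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

EXACT_JT_MAX_N = 12
EXACT_MWU_MAX_PAIRS = 400


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest class, despite the name

    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    method: str  # "exact" or "normal_approx" (or "chi2" for Kruskal-Wallis)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _clean(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U with midrank tie handling.

    Uses exact enumeration when ``n1*n2 <= 400`` and the pooled data holds
    no ties; otherwise the tie-corrected normal approximation.
    """
    x = _clean(x, "x")
    y = _clean(y, "y")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size * y.size <= EXACT_MWU_MAX_PAIRS) and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        test_name="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=(x.size, y.size),
        method="exact" if exact else "normal_approx",
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df)."""
    cleaned = [_clean(g, f"group {i}") for i, g in enumerate(groups)]
    if len(cleaned) < 2:
        raise ValueError("need at least 2 groups")
    if sum(g.size for g in cleaned) < 3:
        raise ValueError("need total n >= 3")
    pooled = np.concatenate(cleaned)
    if np.unique(pooled).size == 1:
        raise ValueError("all values tied across all groups: H is undefined")
    h, p = stats.kruskal(*cleaned)
    return TestResult(
        test_name="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        n_per_group=tuple(g.size for g in cleaned),
        method="chi2",
    )


def _jt_statistic(groups: list[np.ndarray]) -> float:
    """J = sum over i<j of #(x_i < y_j) + 0.5 #(x_i == y_j)."""
    j = 0.0
    for a, b in itertools.combinations(groups, 2):
        diff = b[None, :] - a[:, None]
        j += float(np.count_nonzero(diff > 0)) + 0.5 * float(np.count_nonzero(diff == 0))
    return j


def _jt_null_moments(groups: list[np.ndarray]) -> tuple[float, float]:
    """Null mean and tie-corrected variance of J."""
    sizes = np.array([g.size for g in groups], dtype=float)
    n = sizes.sum()
    pooled = np.concatenate(groups)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)

    mean = (n * n - np.sum(sizes**2)) / 4.0

    term1 = (
        n * (n - 1) * (2 * n + 5)
        - np.sum(sizes * (sizes - 1) * (2 * sizes + 5))
        - np.sum(t * (t - 1) * (2 * t + 5))
    ) / 72.0
    term2 = (
        np.sum(sizes * (sizes - 1) * (sizes - 2))
        * np.sum(t * (t - 1) * (t - 2))
        / (36.0 * n * (n - 1) * (n - 2))
    )
    term3 = (
        np.sum(sizes * (sizes - 1)) * np.sum(t * (t - 1)) / (8.0 * n * (n - 1))
    )
    return mean, term1 + term2 + term3


def _jt_exact_tails(groups: list[np.ndarray], j_obs: float) -> tuple[float, float]:
    """(P(J >= j_obs), P(J <= j_obs)) by full enumeration of assignments."""
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    n = pooled.size
    ge = le = total = 0

    def recurse(remaining: tuple[int, ...], chosen: list[np.ndarray]):
        nonlocal ge, le, total
        depth = len(chosen)
        if depth == len(sizes) - 1:
            last = np.array(sorted(remaining))
            parts = chosen + [pooled[last]]
            j = _jt_statistic(parts)
            total += 1
            if j >= j_obs - 1e-12:
                ge += 1
            if j <= j_obs + 1e-12:
                le += 1
            return
        for combo in itertools.combinations(remaining, sizes[depth]):
            rest = tuple(i for i in remaining if i not in combo)
            recurse(rest, chosen + [pooled[list(combo)]])

    recurse(tuple(range(n)), [])
    return ge / total, le / total


def jonckheere_terpstra(
    ordered_groups, alternative: str = "two_sided", method: str = "auto"
) -> TestResult:
    """Jonckheere-Terpstra trend test across groups in their stated order.

    ``alternative`` is one of ``increasing`` (values grow along the group
    order), ``decreasing``, or ``two_sided`` (twice the smaller tail
    probability, capped at 1).  With ``method="auto"``, exact permutation
    p-values by full enumeration are used when total n <= 12; otherwise a
    tie-corrected normal approximation on J.  ``method="exact"`` or
    ``"normal_approx"`` forces the choice (exact is refused above n=12).
    """
    if alternative not in ("increasing", "decreasing", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if method not in ("auto", "exact", "normal_approx"):
        raise ValueError(f"unknown method {method!r}")
    groups = [_clean(g, f"group {i}") for i, g in enumerate(ordered_groups)]
    if len(groups) < 2:
        raise ValueError("need at least 2 ordered groups")
    j = _jt_statistic(groups)
    n_total = sum(g.size for g in groups)

    if method == "exact" and n_total > EXACT_JT_MAX_N:
        raise ValueError(f"exact enumeration refused above total n={EXACT_JT_MAX_N}")
    if method == "exact" or (method == "auto" and n_total <= EXACT_JT_MAX_N):
        p_ge, p_le = _jt_exact_tails(groups, j)
        method = "exact"
    else:
        mean, var = _jt_null_moments(groups)
        if var <= 0:
            raise ValueError("degenerate data: J has zero null variance")
        sd = math.sqrt(var)
        # continuity correction: J moves in steps of 1 (1/2 under ties)
        p_ge = float(stats.norm.sf((j - 0.5 - mean) / sd))
        p_le = float(stats.norm.cdf((j + 0.5 - mean) / sd))
        method = "normal_approx"

    if alternative == "increasing":
        p = p_ge
    elif alternative == "decreasing":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return TestResult(
        test_name="jonckheere_terpstra",
        statistic=j,
        p_value=p,
        n_per_group=tuple(g.size for g in groups),
        method=method,
        extra={"p_increasing": p_ge, "p_decreasing": p_le},
    )


def run_marker_tests(
    table: pd.DataFrame, markers, class_column: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Kruskal-Wallis + Jonckheere-Terpstra per marker across ordered classes.

    Returns a tidy frame (marker, test, statistic, p, method, robust) where
    ``robust`` flags markers significant at ``alpha`` on *both* tests.
    """
    rows = []
    classes = sorted(table[class_column].dropna().unique())
    for m in markers:
        groups = [
            table.loc[table[class_column] == c, m].dropna().to_numpy() for c in classes
        ]
        kw = kruskal_wallis(groups)
        jt = jonckheere_terpstra(groups)
        robust = bool(kw.p_value <= alpha and jt.p_value <= alpha)
        for r in (kw, jt):
            rows.append(
                {"marker": m, "test": r.test_name, "statistic": r.statistic,
                 "p": r.p_value, "method": r.method, "robust": robust}
            )
    return pd.DataFrame(rows)
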