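"""Cohort statistics: survival summaries, IQR outlier filtering, and the
homoscedasticity-gated two-group comparison.

The comparison rule mirrors spreadsheet/SPSS practice: variance equality is
checked with Levene's test (absolute deviations from the median) at 0.05;
equal-variance groups get a two-sample Student's t-test, unequal-variance
groups fall back to the rank-based Kruskal-Wallis one-factor test.  Quartiles
for outlier fences use linear interpolation of order statistics (the
inclusive method, matching spreadsheet QUARTILE behavior).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ReplicateCounts",
    "SurvivalSummary",
    "ComparisonResult",
    "survival_summary",
    "iqr_filter",
    "compare_groups",
]

LEVENE_ALPHA = 0.05


@dataclass(frozen=True)
class ReplicateCounts:
    """Per-replicate (alive_at_72h, injected) counts for one condition."""

    condition: str
    replicates: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "replicates", tuple(map(tuple, self.replicates)))
        if not self.replicates:
            raise ValueError("at least one replicate is required")
        for alive, injected in self.replicates:
            if injected <= 0:
                raise ValueError(f"injected count must be positive, got {injected}")
            if not 0 <= alive <= injected:
                raise ValueError(f"need 0 <= alive <= injected, got {alive}/{injected}")


@dataclass(frozen=True)
class SurvivalSummary:
    condition: str
    pooled_percent: float  # 100 * total alive / total injected
    sd_of_proportions: float | None  # sample SD of alive/injected, 0-1 scale; None if n=1
    n_replicates: int
    total_alive: int
    total_injected: int


@dataclass(frozen=True)
class ComparisonResult:
    test_used: Literal["student_t", "kruskal_wallis"]
    homoscedastic: bool
    statistic: float
    p_value: float
    alpha: float
    levene_p: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def survival_summary(counts: ReplicateCounts) -> SurvivalSummary:
    """Pooled survival percent and the sample SD of per-replicate proportions.

    The SD uses the n-1 denominator on the 0-1 proportion scale; with a
    single replicate it is reported as None.
    """
    alive = np.array([a for a, _ in counts.replicates], dtype=float)
    injected = np.array([i for _, i in counts.replicates], dtype=float)
    pooled = 100.0 * alive.sum() / injected.sum()
    props = alive / injected
    sd = float(np.std(props, ddof=1)) if props.size > 1 else None
    return SurvivalSummary(
        condition=counts.condition,
        pooled_percent=float(pooled),
        sd_of_proportions=sd,
        n_replicates=props.size,
        total_alive=int(alive.sum()),
        total_injected=int(injected.sum()),
    )


def iqr_filter(values: Sequence[float], k: float = 1.5) -> tuple[list[float], list[float]]:
    """Split values into (kept, outliers) by Tukey fences Q1 - k*IQR, Q3 + k*IQR.

    Quartiles are computed by the inclusive (linear interpolation) method.
    Order is preserved within each returned list.  Requires at least 4 values.
    """
    vals = [float(v) for v in values]
    if len(vals) < 4:
        raise ValueError(f"need at least 4 values for IQR filtering, got {len(vals)}")
    q1, q3 = np.percentile(vals, [25, 75], method="linear")
    lo, hi = q1 - k * (q3 - q1), q3 + k * (q3 - q1)
    kept = [v for v in vals if lo <= v <= hi]
    outliers = [v for v in vals if not (lo <= v <= hi)]
    return kept, outliers


def compare_groups(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> ComparisonResult:
    """Two-group comparison gated on variance equality.

    Levene's test (median-centered) at 0.05 decides the path: homoscedastic
    data get an equal-variance Student's t-test, otherwise Kruskal-Wallis.
    """
    if alpha not in (0.05, 0.01):
        raise ValueError(f"alpha must be 0.05 or 0.01, got {alpha}")
    xa = np.asarray(list(a), dtype=float)
    xb = np.asarray(list(b), dtype=float)
    if xa.size < 3 or xb.size < 3:
        raise ValueError(
            f"each group needs >= 3 values, got {xa.size} and {xb.size}"
        )
    lev_stat, lev_p = sps.levene(xa, xb, center="median")
    homoscedastic = bool(lev_p >= LEVENE_ALPHA)
    if homoscedastic:
        stat, p = sps.ttest_ind(xa, xb, equal_var=True)
        test = "student_t"
    else:
        stat, p = sps.kruskal(xa, xb)
        test = "kruskal_wallis"
    return ComparisonResult(
        test_used=test,
        homoscedastic=homoscedastic,
        statistic=float(stat),
        p_value=float(p),
        alpha=alpha,
        levene_p=float(lev_p),
    )
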