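"""Group comparison of quantified plasma metabolites.

Pooled-variance Student's t-tests on a small panel of absolutely
quantified metabolites (umol/mL plasma), with means +/- SEM, percent
change relative to the low group, and advisory assumption checks
(Shapiro-Wilk normality, two-sided F-ratio variance homogeneity).

Sign convention: t is computed low-minus-high, so a metabolite that is
*higher* at high elevation has a *negative* t.  ``abs_t`` is reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "AssumptionReport",
    "compare_groups",
    "compare_all",
    "check_assumptions",
]


@dataclass(frozen=True)
class GroupComparison:
    metabolite: str
    mean_low: float
    sem_low: float
    mean_high: float
    sem_high: float
    t_statistic: float  # low-minus-high convention
    abs_t: float
    df: float
    p_value: float
    percent_change: float  # relative to the low group
    direction: str  # higher / lower / unchanged


@dataclass(frozen=True)
class AssumptionReport:
    """Advisory pre-test checks; the t-test is run regardless."""

    shapiro_p_low: float
    shapiro_p_high: float
    f_statistic: float
    f_p_value: float
    normal_low: bool
    normal_high: bool
    homogeneous: bool
    degenerate_variance: bool


def _group_values(
    measurements: pd.DataFrame, metabolite: str
) -> tuple[np.ndarray, np.ndarray]:
    sub = measurements[measurements["metabolite"] == metabolite]
    if sub.empty:
        raise ValueError(f"metabolite {metabolite!r} absent from panel data")
    low = sub.loc[sub["group"] == "low", "concentration"].to_numpy(float)
    high = sub.loc[sub["group"] == "high", "concentration"].to_numpy(float)
    for name, vals in (("low", low), ("high", high)):
        if vals.size < 2:
            raise ValueError(
                f"group {name!r} has {vals.size} value(s) for {metabolite!r}; need >= 2"
            )
    return low, high


def compare_groups(
    measurements: pd.DataFrame,
    metabolite: str,
    welch: bool = False,
    alpha: float | None = None,
) -> GroupComparison:
    """Student's t-test (pooled by default; Welch optional) for one panel
    metabolite from a long-format table (individual, group, metabolite,
    concentration).

    ``percent_change = (mean_high - mean_low) / mean_low * 100``.  With
    ``alpha`` set, direction is gated on significance (``unchanged`` when
    p >= alpha); by default direction follows the sign regardless of p.
    """
    low, high = _group_values(measurements, metabolite)
    res = stats.ttest_ind(low, high, equal_var=not welch)
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df) if hasattr(res, "df") else float(low.size + high.size - 2)
    mean_low, mean_high = float(low.mean()), float(high.mean())
    pct = (mean_high - mean_low) / mean_low * 100.0

    if np.isnan(t):  # both groups constant and identical
        t, p = 0.0, 1.0
    if pct == 0 or (alpha is not None and p >= alpha):
        direction = "unchanged"
    else:
        direction = "higher" if pct > 0 else "lower"
    return GroupComparison(
        metabolite=metabolite,
        mean_low=mean_low,
        sem_low=float(stats.sem(low)),
        mean_high=mean_high,
        sem_high=float(stats.sem(high)),
        t_statistic=t,
        abs_t=abs(t),
        df=df,
        p_value=p,
        percent_change=pct,
        direction=direction,
    )


def compare_all(measurements: pd.DataFrame, welch: bool = False,
                alpha: float | None = None) -> pd.DataFrame:
    """One GroupComparison row per metabolite present in the table."""
    rows = [
        asdict(compare_groups(measurements, met, welch=welch, alpha=alpha))
        for met in pd.unique(measurements["metabolite"])
    ]
    return pd.DataFrame(rows)


def check_assumptions(
    values_low: Sequence[float], values_high: Sequence[float], alpha: float = 0.05
) -> AssumptionReport:
    """Shapiro-Wilk normality per group and a two-sided F-ratio test of
    variance homogeneity; flags at ``alpha`` are advisory only.

    A zero-variance group is reported as a degenerate condition (flags
    NaN-safe) rather than raising.
    """
    low = np.asarray(values_low, dtype=float)
    high = np.asarray(values_high, dtype=float)
    for name, vals in (("low", low), ("high", high)):
        if vals.size < 3:
            raise ValueError(f"group {name!r} needs >= 3 values, got {vals.size}")

    var_low = low.var(ddof=1)
    var_high = high.var(ddof=1)
    degenerate = var_low == 0 or var_high == 0

    def _shapiro(v: np.ndarray) -> float:
        if np.ptp(v) == 0:
            return np.nan
        return float(stats.shapiro(v).pvalue)

    sp_low, sp_high = _shapiro(low), _shapiro(high)

    if degenerate:
        if var_low == var_high:  # both zero: trivially homogeneous
            f, f_p = 1.0, 1.0
        else:
            f, f_p = np.inf, 0.0
    else:
        f = float(var_low / var_high)
        dfl, dfh = low.size - 1, high.size - 1
        cdf = stats.f.cdf(f, dfl, dfh)
        f_p = float(2 * min(cdf, 1 - cdf))
    return AssumptionReport(
        shapiro_p_low=sp_low,
        shapiro_p_high=sp_high,
        f_statistic=f,
        f_p_value=f_p,
        normal_low=bool(sp_low > alpha) if not np.isnan(sp_low) else True,
        normal_high=bool(sp_high > alpha) if not np.isnan(sp_high) else True,
        homogeneous=bool(f_p > alpha),
        degenerate_variance=bool(degenerate),
    )
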