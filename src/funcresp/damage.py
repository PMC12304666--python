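"""Trend analysis of survivor counts and defoliation over the 7-day bioassay.

Each treatment arm's response (surviving prey, or cumulative defoliation
percentage) is regressed on day by ordinary least squares, pooling
replicates as independent observations so the standard errors reflect
between-arena variance.  An optional segmented fit splits the series at the
predator-release day, where the survivor trajectory has an obvious
discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .datamodel import DamageSeries, DesignError

__all__ = ["TrendFit", "fit_time_regression", "fit_segmented_regression", "summarize_endpoints"]

RESPONSES = ("survivors", "defoliation_pct")


@dataclass(frozen=True)
class TrendFit:
    """An OLS line of one response on day for one treatment (or segment)."""

    treatment: str
    response: str
    slope: float
    slope_se: float
    slope_cl: tuple[float, float]
    intercept: float
    r_squared: float
    n_points: int
    segment: tuple[int, int] | None = None
    breakpoint_day: int | None = None
    degenerate: bool = False  # constant response: slope 0 with zero SE

    def __post_init__(self) -> None:
        if not self.degenerate and not self.slope_cl[0] <= self.slope <= self.slope_cl[1]:
            raise ValueError("slope CL must contain the estimate")


def _collect(series: Sequence[DamageSeries], response: str, segment: tuple[int, int] | None):
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {RESPONSES}, got {response!r}")
    days, values = [], []
    for s in series:
        for d, v in zip(s.days, getattr(s, response)):
            if segment is None or segment[0] <= d <= segment[1]:
                days.append(d)
                values.append(float(v))
    return np.asarray(days, dtype=float), np.asarray(values, dtype=float)


def fit_time_regression(
    series: Iterable[DamageSeries],
    response: str,
    segment: tuple[int, int] | None = None,
    alpha: float = 0.05,
) -> TrendFit:
    """OLS line of ``response`` on day, replicates pooled.

    Requires at least 3 distinct days in the (optionally restricted)
    segment.  A constant response yields the degenerate fit: slope 0, zero
    SE, r^2 reported as 0, flagged.
    """
    series = list(series)
    if not series:
        raise DesignError("no series to fit")
    treatments = {s.treatment for s in series}
    if len(treatments) > 1:
        raise DesignError(f"expected one treatment, got {treatments}")
    x, y = _collect(series, response, segment)
    if len(np.unique(x)) < 3:
        raise DesignError("at least 3 distinct days are required")

    treatment = series[0].treatment
    if np.allclose(y, y[0]):
        return TrendFit(
            treatment=treatment, response=response, slope=0.0, slope_se=0.0,
            slope_cl=(0.0, 0.0), intercept=float(y[0]), r_squared=0.0,
            n_points=len(y), segment=segment, degenerate=True,
        )
    res = sm.OLS(y, sm.add_constant(x)).fit()
    tq = sps.t.ppf(1.0 - alpha / 2.0, res.df_resid)
    slope, se = float(res.params[1]), float(res.bse[1])
    return TrendFit(
        treatment=treatment, response=response, slope=slope, slope_se=se,
        slope_cl=(slope - tq * se, slope + tq * se),
        intercept=float(res.params[0]), r_squared=float(res.rsquared),
        n_points=len(y), segment=segment,
    )


def fit_segmented_regression(
    series: Iterable[DamageSeries], response: str, alpha: float = 0.05
) -> tuple[TrendFit, TrendFit]:
    """Two OLS segments split at the (shared) predator-release day."""
    series = list(series)
    releases = {s.predator_release_day for s in series}
    if len(releases) != 1 or None in releases:
        raise DesignError("segmented fit needs a single, non-null predator_release_day")
    bp = releases.pop()
    last = max(s.final_day for s in series)
    first = min(s.days[0] for s in series)
    pre = fit_time_regression(series, response, segment=(first, bp), alpha=alpha)
    post = fit_time_regression(series, response, segment=(bp, last), alpha=alpha)
    object.__setattr__(pre, "breakpoint_day", bp)
    object.__setattr__(post, "breakpoint_day", bp)
    return pre, post


def summarize_endpoints(series: Iterable[DamageSeries]) -> pd.DataFrame:
    """Final-day cross-replicate means and SEs per treatment.

    Returns a frame with columns ``treatment, day, survivors_mean,
    survivors_se, defoliation_mean, defoliation_se, n``.  Ragged series
    (unequal final days within a treatment) are an error; the summary is
    invariant to replicate ordering.
    """
    series = list(series)
    if not series:
        raise DesignError("no series to summarize")
    rows = []
    for treatment in sorted({s.treatment for s in series}):
        sub = [s for s in series if s.treatment == treatment]
        final_days = {s.final_day for s in sub}
        if len(final_days) > 1:
            raise DesignError(f"ragged series for treatment {treatment!r}: final days {sorted(final_days)}")
        day = final_days.pop()
        surv = np.array([s.survivors[-1] for s in sub], dtype=float)
        defol = np.array([s.defoliation_pct[-1] for s in sub], dtype=float)
        n = len(sub)
        sem = lambda v: float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "treatment": treatment, "day": day,
                "survivors_mean": float(surv.mean()), "survivors_se": sem(surv),
                "defoliation_mean": float(defol.mean()), "defoliation_se": sem(defol),
                "n": n,
            }
        )
    return pd.DataFrame(rows)
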