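"""Activity-compensation regressions across days.

The compensation hypothesis (an analogue of sleep rebound) predicts that
high activity on one day is followed by reduced activity: a negative
slope when day i+1 activity is regressed on day i activity, or on the
trailing m-day mean activity (m = 2 and 5 probe longer timescales).
Regressions are ordinary least squares per individual; date gaps break
pairing and trailing means require all m days present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .activity import DailyActivitySeries


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int

    def __post_init__(self):
        if np.isfinite(self.r) and abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| cannot exceed 1")


def consecutive_day_pairs(series: DailyActivitySeries) -> np.ndarray:
    """(day i, day i+1) activity pairs; a missing date breaks pairing."""
    if len(series.values) < 2:
        raise ValueError("need at least 2 days")
    step = np.diff(series.dates).astype(int)
    keep = np.flatnonzero(step == 1)
    return np.column_stack([series.values[keep], series.values[keep + 1]])


def lagged_mean_pairs(series: DailyActivitySeries, m: int) -> np.ndarray:
    """x = trailing m-day mean ending day i, y = day i+1 activity.

    Requires the full run day i-m+1 .. day i+1 to be consecutive; m = 1
    reduces to :func:`consecutive_day_pairs`.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    dates = series.dates.astype(int)
    vals = series.values
    pairs = []
    for i in range(m - 1, len(vals) - 1):
        run = dates[i - m + 1 : i + 2]
        if np.all(np.diff(run) == 1):
            pairs.append((vals[i - m + 1 : i + 1].mean(), vals[i + 1]))
    if not pairs:
        raise ValueError(f"no run of {m + 1} consecutive days")
    return np.asarray(pairs)


def fit_compensation_regression(pairs: np.ndarray) -> RegressionResult:
    """OLS of day i+1 activity on the predictor; slope/intercept/r/p by
    the standard closed-form formulas."""
    pairs = np.asarray(pairs, dtype=float)
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for inference")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0:
        return RegressionResult(np.nan, np.nan, np.nan, np.nan, len(pairs))
    fit = stats.linregress(x, y)
    return RegressionResult(
        float(fit.slope), float(fit.intercept), float(fit.rvalue), float(fit.pvalue), len(pairs)
    )


def lagged_mean_regression(series: DailyActivitySeries, m: int) -> RegressionResult:
    """Regression of day i+1 activity on the trailing m-day mean."""
    return fit_compensation_regression(lagged_mean_pairs(series, m))


def compensation_report(series_by_individual, ms=(1, 2, 5)):
    """Per-individual regression results for each trailing window length."""
    import pandas as pd

    rows = []
    for ind, series in series_by_individual.items():
        for m in ms:
            try:
                res = lagged_mean_regression(series, m)
            except ValueError:
                continue
            rows.append(
                {
                    "individual": ind,
                    "m": m,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)
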