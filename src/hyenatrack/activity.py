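"""Hourly activity curves and daily activity fractions.

"Activity" is time spent in the locomotor states WALK or LOPE. Days are
local-time calendar days under a fixed configurable UTC offset (default
+3 h, East Africa Time); an hour has full coverage when every 3 s window
of that hour is present, and a curve is complete only when all 24 hours
do. Partial days at deployment edges are thereby excluded from the
downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ActivityCurve, BehaviorSequence

DEFAULT_UTC_OFFSET_H = 3.0


@dataclass
class DailyActivitySeries:
    """Daily percent-time-active for one individual on complete days."""

    individual: str
    dates: np.ndarray  # datetime64[D], sorted, possibly with gaps
    values: np.ndarray  # percent in [0, 100]

    def __post_init__(self):
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.values = np.asarray(self.values, dtype=float)
        if len(self.dates) != len(self.values):
            raise ValueError("dates and values must align")
        if np.any(np.diff(self.dates).astype(int) <= 0):
            raise ValueError("dates must be strictly increasing")


@dataclass
class HourlyActivitySeries:
    """Hour-by-hour percent activity as a (day x 24) matrix.

    Rows are consecutive local dates; entries are NaN where the hour
    lacks full coverage.
    """

    individual: str
    dates: np.ndarray  # datetime64[D], one per row
    matrix: np.ndarray  # (n_days, 24), NaN for missing hours

    def __post_init__(self):
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.dates), 24):
            raise ValueError("matrix must be (n_days, 24)")

    def flat(self) -> np.ndarray:
        return self.matrix.ravel()


def _hour_table(seq: BehaviorSequence, utc_offset_h: float) -> pd.DataFrame:
    """Per (local date, hour) window counts and active-window counts."""
    local_start = seq.start_time + pd.Timedelta(hours=utc_offset_h)
    start_s = local_start.value / 1e9  # epoch seconds, local clock
    off = start_s / seq.window_s
    wph = 3600.0 / seq.window_s
    if abs(off - round(off)) < 1e-9 and abs(wph - round(wph)) < 1e-9:
        # window-aligned start: pure integer arithmetic on the long axis
        hour_slot = (int(round(off)) + np.arange(seq.n, dtype=np.int64)) // int(round(wph))
    else:
        win_sec = start_s + np.arange(seq.n) * seq.window_s
        hour_slot = np.floor(win_sec / 3600.0).astype(np.int64)
    active = seq.is_active()
    base = hour_slot[0]
    windows = np.bincount(hour_slot - base)
    actives = np.bincount(hour_slot - base, weights=active)
    slots = base + np.flatnonzero(windows)
    g = pd.DataFrame(
        {
            "slot": slots,
            "windows": windows[slots - base],
            "active": actives[slots - base].astype(int),
        }
    )
    g["date"] = np.asarray(g["slot"] // 24, dtype="datetime64[D]")
    g["hour"] = (g["slot"] % 24).astype(int)
    return g


def hourly_activity_curve(
    seq: BehaviorSequence, date, utc_offset_h: float = DEFAULT_UTC_OFFSET_H
) -> ActivityCurve:
    """Activity curve (percent active per hour) for one local calendar day.

    Hours without full coverage (3600 / window_s windows) are NaN and the
    curve is flagged incomplete.
    """
    expected = int(round(3600.0 / seq.window_s))
    g = _hour_table(seq, utc_offset_h)
    date = np.datetime64(pd.Timestamp(date).date())
    day = g[g["date"] == date]
    values = np.full(24, np.nan)
    for _, row in day.iterrows():
        if row["windows"] == expected:
            values[row["hour"]] = 100.0 * row["active"] / row["windows"]
    return ActivityCurve(individual=seq.individual, date=pd.Timestamp(date), values=values)


def activity_curves(seq: BehaviorSequence, utc_offset_h: float = DEFAULT_UTC_OFFSET_H):
    """All activity curves covered by a sequence, one per local date."""
    expected = int(round(3600.0 / seq.window_s))
    g = _hour_table(seq, utc_offset_h)
    curves = []
    for date, day in g.groupby("date", sort=True):
        values = np.full(24, np.nan)
        full = day[day["windows"] == expected]
        values[full["hour"].to_numpy()] = (
            100.0 * full["active"].to_numpy() / full["windows"].to_numpy()
        )
        curves.append(
            ActivityCurve(individual=seq.individual, date=pd.Timestamp(date), values=values)
        )
    return curves


def mean_daily_pattern(curves) -> np.ndarray:
    """Per-hour mean activity across an individual's complete days."""
    complete = [c.values for c in curves if c.complete]
    if not complete:
        raise ValueError("no complete days")
    return np.mean(complete, axis=0)


def daily_activity_fraction(
    seq: BehaviorSequence, date, utc_offset_h: float = DEFAULT_UTC_OFFSET_H
) -> float:
    """Percent of a fully covered local day's windows in an active state.

    Raises if the day is not fully covered (partial deployment days are
    excluded from downstream statistics).
    """
    curve = hourly_activity_curve(seq, date, utc_offset_h)
    if not curve.complete:
        raise ValueError(f"day {date} not fully covered")
    # equal window counts per hour make this the simple mean of hourly values
    return float(np.mean(curve.values))


def daily_activity_series(
    seq: BehaviorSequence, utc_offset_h: float = DEFAULT_UTC_OFFSET_H
) -> DailyActivitySeries:
    """Daily activity percentages over all complete days of a deployment."""
    curves = [c for c in activity_curves(seq, utc_offset_h) if c.complete]
    if not curves:
        raise ValueError("no complete days in sequence")
    dates = np.asarray([np.datetime64(c.date.date()) for c in curves], dtype="datetime64[D]")
    values = np.asarray([np.mean(c.values) for c in curves])
    return DailyActivitySeries(seq.individual, dates, values)


def hourly_activity_series(
    seq: BehaviorSequence, utc_offset_h: float = DEFAULT_UTC_OFFSET_H
) -> HourlyActivitySeries:
    """Deployment-long hourly activity as a (day x 24) matrix."""
    curves = activity_curves(seq, utc_offset_h)
    if not curves:
        raise ValueError("empty sequence")
    d0 = np.datetime64(curves[0].date.date())
    d1 = np.datetime64(curves[-1].date.date())
    dates = np.arange(d0, d1 + 1)
    matrix = np.full((len(dates), 24), np.nan)
    for c in curves:
        matrix[(np.datetime64(c.date.date()) - d0).astype(int)] = c.values
    return HourlyActivitySeries(seq.individual, dates, matrix)


def pooled_daily_pattern(seq: BehaviorSequence, utc_offset_h: float = DEFAULT_UTC_OFFSET_H) -> np.ndarray:
    """Per-hour percent activity pooling all windows across days (the
    figure-style summary; per-day curves feed the statistics)."""
    g = _hour_table(seq, utc_offset_h)
    out = np.full(24, np.nan)
    for h, grp in g.groupby("hour"):
        out[h] = 100.0 * grp["active"].sum() / grp["windows"].sum()
    return out


def curves_to_frame(curves) -> pd.DataFrame:
    """Serialize curves as individual, date, h00..h23, complete."""
    rows = []
    for c in curves:
        row = {"individual": c.individual, "date": c.date.date(), "complete": c.complete}
        row.update({f"h{h:02d}": c.values[h] for h in range(24)})
        rows.append(row)
    return pd.DataFrame(rows)
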