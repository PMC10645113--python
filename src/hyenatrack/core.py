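"""Shared data containers for the hyena biologging pipeline.

All timestamps are timezone-naive UTC. Acceleration is in units of g
(gravity magnitude 1); positions are metric planar coordinates in metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The five-state ethogram used for behavioural labelling.
STATES = ("WALK", "LOPE", "STAND", "LYING", "LYUP")

#: States counted as "active" for activity curves and daily fractions.
ACTIVE_STATES = ("WALK", "LOPE")

#: Non-locomotor states.
STATIC_STATES = ("STAND", "LYING", "LYUP")

AXES = ("surge", "sway", "heave")


@dataclass
class AccelTrace:
    """Regularly sampled tri-axial acceleration for one individual.

    Parameters
    ----------
    start_time : pd.Timestamp
        Time of the first sample (UTC, tz-naive).
    rate : float
        Sampling rate in Hz.
    samples : np.ndarray, shape (n, 3)
        Surge, sway, heave in g. No missing samples; gaps must be
        represented by splitting into separate traces.
    individual : str
        Identifier of the tagged animal.
    """

    start_time: pd.Timestamp
    rate: float
    samples: np.ndarray
    individual: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        self.start_time = pd.Timestamp(self.start_time)

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n / self.rate


@dataclass
class GpsTrack:
    """1 Hz GPS positions on a regular grid with validity flags.

    Positions are local planar metric coordinates; invalid fixes hold
    NaN or stale values and are ignored wherever ``valid`` is False.
    """

    start_time: pd.Timestamp
    positions: np.ndarray  # (n, 2) metres
    valid: np.ndarray = None  # (n,) bool
    rate: float = 1.0
    individual: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")
        if self.valid is None:
            self.valid = np.ones(len(self.positions), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape[0] != self.positions.shape[0]:
            raise ValueError("valid flags must match positions length")
        self.start_time = pd.Timestamp(self.start_time)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def times_s(self) -> np.ndarray:
        """Seconds since start for each fix."""
        return np.arange(self.n) / self.rate


@dataclass
class BehaviorSequence:
    """Per-window behavioural states (true or predicted) on a fixed grid."""

    individual: str
    start_time: pd.Timestamp
    states: np.ndarray  # (n,) strings from STATES
    window_s: float = 3.0
    validate: bool = True  # generators constructing from STATES may skip

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="U8")
        self.start_time = pd.Timestamp(self.start_time)
        if self.validate:
            unknown = set(np.unique(self.states)) - set(STATES)
            if unknown:
                raise ValueError(f"unknown states: {sorted(unknown)}")

    @property
    def n(self) -> int:
        return len(self.states)

    def window_starts_s(self) -> np.ndarray:
        return np.arange(self.n) * self.window_s

    def is_active(self) -> np.ndarray:
        # direct comparisons beat np.isin on long string arrays
        out = self.states == ACTIVE_STATES[0]
        for s in ACTIVE_STATES[1:]:
            out |= self.states == s
        return out


@dataclass
class Audit:
    """Ground-truth behavioural-state intervals for one observation bout.

    ``intervals`` has columns ``start_s``, ``stop_s`` (seconds relative to
    the matching trace start) and ``state``.
    """

    audit_id: str
    individual: str
    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"start_s", "stop_s", "state"}
        if not required.issubset(self.intervals.columns):
            raise ValueError(f"intervals must have columns {sorted(required)}")
        unknown = set(self.intervals["state"]) - set(STATES)
        if unknown:
            raise ValueError(f"unknown states in audit: {sorted(unknown)}")


@dataclass
class ActivityCurve:
    """Percent time active for each hour of one individual-day.

    ``values`` has 24 entries in [0, 100]; hours without coverage are NaN
    and make the curve incomplete.
    """

    individual: str
    date: pd.Timestamp
    values: np.ndarray
    complete: bool = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (24,):
            raise ValueError("values must have 24 entries")
        if self.complete is None:
            self.complete = bool(np.all(np.isfinite(self.values)))
        self.date = pd.Timestamp(self.date).normalize()


def unique_pairs(items):
    """All n(n-1)/2 unordered pairs, in stable order."""
    items = list(items)
    return [(a, b) for i, a in enumerate(items) for b in items[i + 1 :]]
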