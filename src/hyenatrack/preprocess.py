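"""Reading and cleaning of accelerometer and GPS streams.

Accelerometer traces are downsampled by block averaging (1000 Hz field
recordings to 25 Hz for analysis). GPS tracks are cleaned by (i) removing
fixes implying unrealistic speeds, thresholded at a high percentile of
the per-deployment speed distribution, and (ii) linearly interpolating
short gaps — shorter than 5 s in duration OR less than 5 m in endpoint
displacement.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .core import AccelTrace, Audit, GpsTrack

EARTH_RADIUS_M = 6371000.0


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_accel_csv(path, individual: str = "") -> AccelTrace:
    """Read an accelerometer CSV (timestamp, surge, sway, heave in g).

    The sampling rate is inferred from the first two timestamps; the grid
    is assumed regular (gaps must be split upstream).
    """
    df = pd.read_csv(path)
    ts = pd.to_datetime(df["timestamp"], utc=True).dt.tz_localize(None)
    if len(ts) < 2:
        raise ValueError("accelerometer CSV needs at least 2 samples")
    dt = (ts.iloc[1] - ts.iloc[0]).total_seconds()
    rate = 1.0 / dt
    return AccelTrace(
        start_time=ts.iloc[0],
        rate=round(rate, 6),
        samples=df[["surge", "sway", "heave"]].to_numpy(float),
        individual=individual,
    )


def read_gps_csv(path, individual: str = "", dialect: str = "xy") -> GpsTrack:
    """Read a GPS CSV at 1 Hz.

    dialect "xy": columns timestamp, x, y (local planar metres).
    dialect "latlon": columns timestamp, lat, lon (decimal degrees),
    projected to a local equirectangular plane about the track centroid.
    """
    df = pd.read_csv(path)
    ts = pd.to_datetime(df["timestamp"], utc=True).dt.tz_localize(None)
    if dialect == "xy":
        pos = df[["x", "y"]].to_numpy(float)
    elif dialect == "latlon":
        pos = project_latlon(df["lat"].to_numpy(float), df["lon"].to_numpy(float))
    else:
        raise ValueError("dialect must be 'xy' or 'latlon'")
    valid = np.all(np.isfinite(pos), axis=1)
    return GpsTrack(start_time=ts.iloc[0], positions=pos, valid=valid, individual=individual)


def read_audit(path, individual: str = "", trace_start=None, audit_id: str = None) -> Audit:
    """Read a tab-separated audit file (start, stop, state).

    Times may be ISO timestamps (converted to seconds relative to
    ``trace_start``) or plain seconds.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]

    def to_seconds(col):
        try:
            return df[col].astype(float).to_numpy()
        except (ValueError, TypeError):
            if trace_start is None:
                raise ValueError("trace_start required for timestamped audits")
            t = pd.to_datetime(df[col], utc=True).dt.tz_localize(None)
            return (t - pd.Timestamp(trace_start)).dt.total_seconds().to_numpy()

    out = pd.DataFrame(
        {
            "start_s": to_seconds("start"),
            "stop_s": to_seconds("stop"),
            "state": df["state"].str.strip().str.upper(),
        }
    )
    import os

    return Audit(audit_id or os.path.basename(str(path)), individual, out)


def project_latlon(lat, lon) -> np.ndarray:
    """Equirectangular projection about the track centroid (metres)."""
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    lat0 = np.nanmean(lat)
    lon0 = np.nanmean(lon)
    x = np.radians(lon - lon0) * np.cos(np.radians(lat0)) * EARTH_RADIUS_M
    y = np.radians(lat - lat0) * EARTH_RADIUS_M
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# Accelerometer
# ---------------------------------------------------------------------------

def downsample_accel(trace: AccelTrace, target_rate: float) -> AccelTrace:
    """Block-mean decimation to ``target_rate``.

    Each output sample is the mean of rate/target_rate consecutive input
    samples (mild anti-aliasing that preserves dynamic-acceleration
    energy better than naive decimation). The factor must be an integer.
    """
    factor = trace.rate / target_rate
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"target_rate {target_rate} must evenly divide trace rate {trace.rate}"
        )
    f = int(round(factor))
    n_out = trace.n // f
    blocks = trace.samples[: n_out * f].reshape(n_out, f, 3)
    return replace(trace, rate=float(target_rate), samples=blocks.mean(axis=1))


# ---------------------------------------------------------------------------
# GPS
# ---------------------------------------------------------------------------

def gps_speeds(track: GpsTrack) -> np.ndarray:
    """Speed (m/s) at each valid fix from the previous valid fix; NaN for
    invalid fixes and the first valid fix."""
    speeds = np.full(track.n, np.nan)
    vidx = np.flatnonzero(track.valid)
    if len(vidx) >= 2:
        pos = track.positions[vidx]
        dt = np.diff(vidx) / track.rate
        dist = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        speeds[vidx[1:]] = dist / dt
    return speeds


def filter_gps_speed(track: GpsTrack, percentile: float = 99.95, threshold: float = None):
    """Invalidate fixes whose approach speed exceeds a percentile of the
    deployment's speed distribution.

    Returns ``(track, threshold_m_per_s)``. Pass ``threshold`` to reuse a
    previously computed (or pooled multi-individual) cut-off, which also
    makes the operation idempotent at that fixed value.
    """
    if np.count_nonzero(track.valid) < 2:
        raise ValueError("speed filtering needs at least 2 valid fixes")
    speeds = gps_speeds(track)
    finite = speeds[np.isfinite(speeds)]
    if threshold is None:
        threshold = float(np.percentile(finite, percentile))
    valid = track.valid & ~(speeds > threshold)
    return replace(track, valid=valid), float(threshold)


def pooled_speed_threshold(tracks, percentile: float = 99.95) -> float:
    """Speed cut-off from the pooled speed distribution of several
    deployments."""
    pooled = np.concatenate([gps_speeds(t) for t in tracks])
    pooled = pooled[np.isfinite(pooled)]
    if len(pooled) == 0:
        raise ValueError("no speeds available")
    return float(np.percentile(pooled, percentile))


def interpolate_gps_gaps(
    track: GpsTrack, max_duration: float = 5.0, max_displacement: float = 5.0
) -> GpsTrack:
    """Fill short gaps by linear interpolation.

    A maximal run of invalid fixes bounded by valid fixes is filled iff
    its duration (time between the bounding valid fixes) is below
    ``max_duration`` OR the displacement between the bounding fixes is
    below ``max_displacement``. Leading/trailing gaps are never filled;
    valid fixes are never altered.
    """
    valid = track.valid.copy()
    pos = track.positions.copy()
    vidx = np.flatnonzero(valid)
    if len(vidx) < 2:
        return replace(track, positions=pos, valid=valid)
    # gaps are between consecutive valid fixes with index difference > 1
    gap_at = np.flatnonzero(np.diff(vidx) > 1)
    for g in gap_at:
        a, b = vidx[g], vidx[g + 1]
        duration = (b - a) / track.rate
        displacement = np.linalg.norm(pos[b] - pos[a])
        if duration < max_duration or displacement < max_displacement:
            frac = (np.arange(a + 1, b) - a) / (b - a)
            pos[a + 1 : b] = pos[a][None, :] + frac[:, None] * (pos[b] - pos[a])[None, :]
            valid[a + 1 : b] = True
    return replace(track, positions=pos, valid=valid)
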