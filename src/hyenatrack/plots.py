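"""Minimal figure helpers (daily pattern, synchrony panels).

Twilight shading is a plotting input (sunrise/sunset hours supplied by
the caller), never computed here.
"""

from __future__ import annotations

import numpy as np


def plot_daily_pattern(ax, pattern, sunrise_h: float = None, sunset_h: float = None, **kwargs):
    """24 h activity pattern with optional night shading."""
    hours = np.arange(24) + 0.5
    ax.plot(hours, pattern, **kwargs)
    if sunrise_h is not None and sunset_h is not None:
        ax.axvspan(0, sunrise_h, color="0.85", zorder=0)
        ax.axvspan(sunset_h, 24, color="0.85", zorder=0)
    ax.set_xlim(0, 24)
    ax.set_xlabel("hour of day (local)")
    ax.set_ylabel("% time active")
    return ax


def plot_sync_panel(ax, result, bins: int = 20):
    """Null histogram with the observed synchronization score marked."""
    ax.hist(result.null_scores, bins=bins, color="tab:blue", alpha=0.7)
    ax.axvline(result.observed, color="tab:red", lw=2)
    ax.set_title(
        f"{result.pair[0]}-{result.pair[1]}"
        + (" (synchronized)" if result.synchronized else ""),
        fontsize=9,
    )
    ax.set_xlabel("synchronization score")
    return ax
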