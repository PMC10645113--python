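"""Individuality of daily activity patterns: statistic and permutation test.

Variability between two individual-days is the sum of squared
differences between their 24-hour activity curves. The individuality
statistic is the mean across-individual variability (different
individuals, different days) minus the mean within-individual
variability (same individual, different days); positive values mean
individuals are more consistent with themselves than with each other.

The null is built from "pseudo-individuals": each permutation reshuffles,
within every calendar date, the assignment of that date's curves among
the individuals holding data that date, so per-individual curve counts
and per-date curve multisets are preserved. The one-tailed p-value is
the fraction of null statistics at least as large as the observed one,
reported as "< 1/N" when no null value reaches it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ActivityCurve


@dataclass
class IndividualityResult:
    within_mean: float
    across_mean: float
    statistic: float
    null_distribution: np.ndarray
    p_one_tailed: float
    p_report: str

    def __post_init__(self):
        if not 0 <= self.p_one_tailed <= 1:
            raise ValueError("p must be in [0, 1]")


def curve_distance(a: ActivityCurve, b: ActivityCurve) -> float:
    """Sum of squared hourly differences (squared-percent units)."""
    if not (a.complete and b.complete):
        raise ValueError("both curves must be complete")
    d = a.values - b.values
    return float(d @ d)


def _curve_arrays(curves):
    curves = [c for c in curves if c.complete]
    if len(curves) < 2:
        raise ValueError("need at least 2 complete curves")
    X = np.stack([c.values for c in curves])
    inds = np.asarray([c.individual for c in curves])
    dates = np.asarray([np.datetime64(c.date.date()) for c in curves])
    return X, inds, dates


def _pairwise_sq_distances(X):
    diff = X[:, None, :] - X[None, :, :]
    return (diff**2).sum(axis=2)


def _stat_from_masks(D, inds, diff_date, include_same_date_across=False):
    same_ind = inds[:, None] == inds[None, :]
    within = same_ind & diff_date
    across = ~same_ind & (True if include_same_date_across else diff_date)
    iu = np.triu(np.ones_like(same_ind), k=1).astype(bool)
    within &= iu
    across &= iu
    if not within.any() or not across.any():
        raise ValueError("insufficient curve pairs for the statistic")
    within_mean = D[within].mean()
    across_mean = D[across].mean()
    return within_mean, across_mean, across_mean - within_mean


def individuality_statistic(curves, include_same_date_across: bool = False):
    """(within_mean, across_mean, statistic) over complete curves.

    Same-date cross-individual pairs are excluded by default (both the
    within and across means compare different days only).
    """
    X, inds, dates = _curve_arrays(curves)
    if len(np.unique(inds)) < 2:
        raise ValueError("need curves from at least 2 individuals")
    D = _pairwise_sq_distances(X)
    diff_date = dates[:, None] != dates[None, :]
    return _stat_from_masks(D, inds, diff_date, include_same_date_across)


def _date_shuffle(rng, inds, dates):
    """Pseudo-individual labels: per date, permute that date's curve
    assignment among the individuals present that date."""
    out = inds.copy()
    for d in np.unique(dates):
        sel = np.flatnonzero(dates == d)
        if len(sel) > 1:
            out[sel] = out[sel[rng.permutation(len(sel))]]
    return out


def permutation_test_individuality(
    curves,
    n_permutations: int = 5000,
    seed: int = 0,
    include_same_date_across: bool = False,
    add_one: bool = False,
) -> IndividualityResult:
    """Date-wise shuffle test of the individuality statistic.

    ``add_one`` switches to the (b+1)/(N+1) p-value convention; the
    default is b/N with zero exceedances reported as "< 1/N".
    """
    X, inds, dates = _curve_arrays(curves)
    if len(np.unique(inds)) < 2:
        raise ValueError("need curves from at least 2 individuals")
    D = _pairwise_sq_distances(X)
    diff_date = dates[:, None] != dates[None, :]
    w, a, observed = _stat_from_masks(D, inds, diff_date, include_same_date_across)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        labels = _date_shuffle(rng, inds, dates)
        null[k] = _stat_from_masks(D, labels, diff_date, include_same_date_across)[2]
    exceed = int(np.sum(null >= observed))
    if add_one:
        p = (exceed + 1) / (n_permutations + 1)
        report = f"{p:.6g}"
    else:
        p = exceed / n_permutations
        report = f"< 1/{n_permutations}" if exceed == 0 else f"{p:.6g}"
    return IndividualityResult(w, a, observed, null, p, report)


def per_individual_variability(curves, n_permutations: int = 1000, seed: int = 0):
    """Per-individual follow-up: overall mean different-day variability
    minus the individual's within variability, with the same date-wise
    shuffle null. Returns {individual: (statistic, p_one_tailed)}.

    A negative statistic (p near 1) marks an individual whose day-to-day
    variability exceeds the population's overall variability.
    """
    X, inds, dates = _curve_arrays(curves)
    D = _pairwise_sq_distances(X)
    diff_date = dates[:, None] != dates[None, :]
    iu = np.triu(np.ones_like(diff_date), k=1).astype(bool)
    overall = D[diff_date & iu].mean()

    def stats_for(labels):
        out = {}
        for ind in np.unique(inds):
            mask = (labels[:, None] == ind) & (labels[None, :] == ind) & diff_date & iu
            out[ind] = overall - D[mask].mean() if mask.any() else np.nan
        return out

    observed = stats_for(inds)
    rng = np.random.default_rng(seed)
    exceed = {ind: 0 for ind in observed}
    for _ in range(n_permutations):
        null = stats_for(_date_shuffle(rng, inds, dates))
        for ind in exceed:
            if null[ind] >= observed[ind]:
                exceed[ind] += 1
    return {
        ind: (float(observed[ind]), exceed[ind] / n_permutations) for ind in observed
    }
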