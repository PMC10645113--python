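"""Behavioural-state classification from windowed accelerometer features.

Every fully audited, non-straddling 3 s window contributes one row of 16
features — {min, max, mean, variance} of {surge, sway, heave, VeDBA} —
and a ground-truth state from the five-state ethogram. Classifiers are
scikit-learn estimators at library defaults (random forest, RBF-kernel
SVM, k-NN), with training-fold feature standardization for the two
distance-based models. Three validation schemes of increasing stringency
are provided: a random 85/15 split, leave-one-audit-out, and
leave-one-individual-out; the grouped schemes guard against the
spuriously high accuracies that within-bout correlation produces under
random splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import STATES, AccelTrace, Audit, BehaviorSequence
from .vedba import VedbaSeries, compute_vedba

CHANNELS = ("surge", "sway", "heave", "vedba")
STATS = ("min", "max", "mean", "var")
FEATURE_NAMES = tuple(f"{c}_{s}" for c in CHANNELS for s in STATS)


@dataclass
class EvaluationReport:
    """Accuracy and row-normalized confusion matrix for one scheme.

    Confusion rows are true states, columns predicted states; rows are
    fractions summing to 1 where the true state occurs (NaN otherwise).
    """

    scheme: str
    accuracy: float
    confusion: pd.DataFrame
    counts: pd.DataFrame
    notes: list = field(default_factory=list)


def extract_features(window_samples: np.ndarray, window_vedba: np.ndarray) -> np.ndarray:
    """16-vector of {min, max, mean, population variance} per channel."""
    window_samples = np.asarray(window_samples, dtype=float)
    window_vedba = np.asarray(window_vedba, dtype=float)
    if window_samples.ndim != 2 or window_samples.shape[1] != 3:
        raise ValueError("window_samples must have shape (k, 3)")
    if len(window_vedba) != len(window_samples):
        raise ValueError("VeDBA values must match the window sample count")
    cols = [window_samples[:, 0], window_samples[:, 1], window_samples[:, 2], window_vedba]
    out = np.empty(16)
    for i, c in enumerate(cols):
        out[4 * i : 4 * i + 4] = (c.min(), c.max(), c.mean(), c.var())
    return out


def _windowed_features(trace: AccelTrace, vedba: VedbaSeries, window_s: float = 3.0):
    """Feature matrix for all full non-overlapping windows of a trace."""
    spw = int(round(window_s * trace.rate))
    if abs(spw - window_s * trace.rate) > 1e-9:
        raise ValueError("window_s * rate must be an integer sample count")
    n_win = trace.n // spw
    if n_win == 0:
        raise ValueError("trace shorter than one window")
    x = trace.samples[: n_win * spw].reshape(n_win, spw, 3)
    v = vedba.values[: n_win * spw].reshape(n_win, spw)
    feats = np.empty((n_win, 16))
    for i in range(3):
        ch = x[:, :, i]
        feats[:, 4 * i + 0] = ch.min(axis=1)
        feats[:, 4 * i + 1] = ch.max(axis=1)
        feats[:, 4 * i + 2] = ch.mean(axis=1)
        feats[:, 4 * i + 3] = ch.var(axis=1)
    feats[:, 12] = v.min(axis=1)
    feats[:, 13] = v.max(axis=1)
    feats[:, 14] = v.mean(axis=1)
    feats[:, 15] = v.var(axis=1)
    return feats


def build_training_table(
    audits, traces, vedba_series=None, window_s: float = 3.0
) -> pd.DataFrame:
    """One labelled feature row per fully audited 3 s window.

    ``audits`` is an iterable of :class:`Audit`; ``traces`` maps
    individual id to its :class:`AccelTrace`. Windows straddling a state
    change (or only partially audited) are dropped. Rows carry the audit
    and individual ids needed by the grouped validation schemes.
    """
    vedba_series = vedba_series or {}
    rows = []
    for audit in audits:
        if audit.individual not in traces:
            raise ValueError(f"no trace for individual {audit.individual}")
        trace = traces[audit.individual]
        if audit.individual not in vedba_series:
            vedba_series[audit.individual] = compute_vedba(trace)
        vedba = vedba_series[audit.individual]
        feats = _windowed_features(trace, vedba, window_s)
        n_win = len(feats)
        for _, iv in audit.intervals.iterrows():
            if iv["stop_s"] > trace.duration_s + 1e-9 or iv["start_s"] < -1e-9:
                raise ValueError(
                    f"audit {audit.audit_id} interval outside trace time range"
                )
            first = int(np.ceil(iv["start_s"] / window_s - 1e-9))
            last = int(np.floor(iv["stop_s"] / window_s + 1e-9))  # exclusive
            for w in range(max(first, 0), min(last, n_win)):
                rows.append(
                    (audit.individual, audit.audit_id, w * window_s, iv["state"], feats[w])
                )
    if not rows:
        return pd.DataFrame(
            columns=["individual", "audit", "window_start_s", "state", *FEATURE_NAMES]
        )
    table = pd.DataFrame(
        {
            "individual": [r[0] for r in rows],
            "audit": [r[1] for r in rows],
            "window_start_s": [r[2] for r in rows],
            "state": [r[3] for r in rows],
        }
    )
    table[list(FEATURE_NAMES)] = np.vstack([r[4] for r in rows])
    return table


def train_classifier(table: pd.DataFrame, kind: str = "rf", seed: int = 0, scaling: bool = True):
    """Fit a behavioural-state classifier at library defaults.

    rf: 100 trees, Gini impurity, unlimited depth. svm: RBF kernel,
    C = 1.0. knn: k = 5, Euclidean. SVM and k-NN get a training-fitted
    StandardScaler unless ``scaling`` is False.
    """
    X = table[list(FEATURE_NAMES)].to_numpy(float)
    y = table["state"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain at least 2 classes")
    model = make_classifier(kind, seed, scaling)
    model.fit(X, y)
    return model


def make_classifier(kind: str = "rf", seed: int = 0, scaling: bool = True):
    if kind == "rf":
        return RandomForestClassifier(random_state=seed)
    if kind == "svm":
        est = SVC(random_state=seed)
    elif kind == "knn":
        est = KNeighborsClassifier()
    else:
        raise ValueError("kind must be one of 'rf', 'svm', 'knn'")
    if scaling:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


def _report(scheme: str, y_true, y_pred, notes=None) -> EvaluationReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    counts = pd.DataFrame(0, index=list(STATES), columns=list(STATES), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts.loc[t, p] += 1
    totals = counts.sum(axis=1)
    confusion = counts.div(totals.where(totals > 0), axis=0)
    accuracy = float(np.mean(y_true == y_pred))
    return EvaluationReport(scheme, accuracy, confusion, counts, notes or [])


def evaluate_random_split(
    table: pd.DataFrame, test_fraction: float = 0.15, kind: str = "rf", seed: int = 0
) -> EvaluationReport:
    """Train on a random (1 - test_fraction) share of windows, test on the
    rest (unstratified)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    train, test = train_test_split(
        table, test_size=test_fraction, random_state=seed, shuffle=True
    )
    model = train_classifier(train, kind, seed)
    y_pred = model.predict(test[list(FEATURE_NAMES)].to_numpy(float))
    notes = []
    missing = set(table["state"]) - set(test["state"])
    if missing:
        notes.append(f"states absent from test split: {sorted(missing)}")
    return _report("random_split", test["state"], y_pred, notes)


def _grouped_evaluation(table: pd.DataFrame, group_col: str, scheme: str, kind: str, seed: int):
    groups = table[group_col].unique()
    if len(groups) < 2:
        raise ValueError(f"need at least 2 {group_col}s for {scheme} validation")
    y_true, y_pred, notes = [], [], []
    for g in groups:
        train = table[table[group_col] != g]
        test = table[table[group_col] == g]
        missing = set(test["state"]) - set(train["state"])
        if missing:
            notes.append(f"fold {g}: training set lacks {sorted(missing)}")
        model = train_classifier(train, kind, seed)
        y_true.append(test["state"].to_numpy())
        y_pred.append(model.predict(test[list(FEATURE_NAMES)].to_numpy(float)))
    return _report(scheme, np.concatenate(y_true), np.concatenate(y_pred), notes)


def evaluate_leave_one_audit_out(table: pd.DataFrame, kind: str = "rf", seed: int = 0) -> EvaluationReport:
    """One fold per audit; predictions pooled across folds."""
    return _grouped_evaluation(table, "audit", "audit_wise", kind, seed)


def evaluate_leave_one_individual_out(table: pd.DataFrame, kind: str = "rf", seed: int = 0) -> EvaluationReport:
    """One fold per individual; predictions pooled across folds."""
    return _grouped_evaluation(table, "individual", "individual_wise", kind, seed)


def predict_sequence(
    model, trace: AccelTrace, vedba: VedbaSeries = None, window_s: float = 3.0
) -> BehaviorSequence:
    """Predict one state per non-overlapping 3 s window over a full trace."""
    vedba = vedba or compute_vedba(trace)
    feats = _windowed_features(trace, vedba, window_s)
    states = model.predict(feats)
    return BehaviorSequence(
        individual=trace.individual,
        start_time=trace.start_time,
        states=states,
        window_s=window_s,
    )


def activity_level_composition(seq: BehaviorSequence, level_labels) -> pd.DataFrame:
    """Fraction of each activity level's windows in each behavioural state.

    Rows are activity levels (in first-appearance-of-label order low to
    high when produced by :func:`hyenatrack.vedba.assign_activity_levels`),
    columns the five states; each occupied row sums to 1.
    """
    level_labels = np.asarray(level_labels)
    if len(level_labels) != seq.n:
        raise ValueError("levels and sequence must align window-for-window")
    levels = pd.unique(level_labels)
    out = pd.DataFrame(0.0, index=levels, columns=list(STATES))
    for lv in levels:
        sel = seq.states[level_labels == lv]
        for s, c in zip(*np.unique(sel, return_counts=True)):
            out.loc[lv, s] = c / len(sel)
    return out
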