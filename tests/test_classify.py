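"""Feature extraction, training-table construction and validation schemes."""

import numpy as np
import pandas as pd
import pytest

import hyenatrack as ht
from hyenatrack import classify as cl
from hyenatrack.vedba import compute_vedba


def brute_force_features(samples, vedba):
    out = []
    for col in [samples[:, 0], samples[:, 1], samples[:, 2], np.asarray(vedba)]:
        n = len(col)
        mean = sum(col) / n
        var = sum((c - mean) ** 2 for c in col) / n  # population variance
        out.extend([min(col), max(col), mean, var])
    return np.asarray(out)


class TestExtractFeatures:
    def test_constant_window(self):
        samples = np.tile([1.0, 0.0, 0.0], (75, 1))
        f = cl.extract_features(samples, np.zeros(75))
        assert np.allclose(f, [1, 1, 1, 0] + [0] * 12)

    def test_ramp_pins_population_variance(self):
        samples = np.zeros((75, 3))
        samples[:, 0] = np.arange(75.0)
        f = cl.extract_features(samples, np.zeros(75))
        assert f[0] == 0.0 and f[1] == 74.0 and f[2] == 37.0
        assert f[3] == pytest.approx(np.arange(75.0).var())  # divide-by-n

    def test_sixteen_features_matching_brute_force(self):
        rng = np.random.default_rng(21)
        samples = rng.normal(size=(75, 3))
        vedba = rng.gamma(2.0, 1.0, 75)
        f = cl.extract_features(samples, vedba)
        assert len(f) == 16
        assert np.allclose(f, brute_force_features(samples, vedba), rtol=1e-12)


class TestTrainingTable:
    def make_trace(self, n_windows, rate=25.0):
        seq = ht.BehaviorSequence("H00", "2017-01-01", ["WALK"] * n_windows)
        return ht.generate_accel_trace(seq, rate=rate, seed=2)

    def test_thirty_seconds_of_walk_gives_ten_rows(self):
        trace = self.make_trace(10)
        audit = ht.Audit(
            "a0", "H00", pd.DataFrame({"start_s": [0.0], "stop_s": [30.0], "state": ["WALK"]})
        )
        table = cl.build_training_table([audit], {"H00": trace})
        assert len(table) == 10
        assert (table["state"] == "WALK").all()

    def test_straddling_window_dropped(self):
        trace = self.make_trace(2)
        audit = ht.Audit(
            "a0",
            "H00",
            pd.DataFrame(
                {"start_s": [0.0, 4.0], "stop_s": [4.0, 6.0], "state": ["WALK", "STAND"]}
            ),
        )
        table = cl.build_training_table([audit], {"H00": trace})
        # window [0,3) inside WALK kept; [3,6) straddles the change at 4 s
        assert table["window_start_s"].tolist() == [0.0]

    def test_empty_audit_set(self):
        table = cl.build_training_table([], {})
        assert table.empty

    def test_audit_outside_trace_rejected(self):
        trace = self.make_trace(2)
        audit = ht.Audit(
            "a0", "H00", pd.DataFrame({"start_s": [0.0], "stop_s": [60.0], "state": ["WALK"]})
        )
        with pytest.raises(ValueError, match="outside"):
            cl.build_training_table([audit], {"H00": trace})


def balanced_random_table(rng, n_per_class=60):
    """5 balanced classes with informative features."""
    rows = []
    for k, state in enumerate(ht.STATES):
        X = rng.normal(loc=k, scale=0.2, size=(n_per_class, 16))
        for x in X:
            rows.append({"individual": "H00", "audit": f"a{k % 2}", "state": state,
                         **dict(zip(cl.FEATURE_NAMES, x))})
    df = pd.DataFrame(rows)
    df["window_start_s"] = np.arange(len(df)) * 3.0
    return df


class TestTraining:
    def test_separable_table_fits_perfectly(self):
        rng = np.random.default_rng(30)
        table = balanced_random_table(rng)
        for kind in ("rf", "svm", "knn"):
            model = cl.train_classifier(table, kind, seed=0)
            acc = np.mean(model.predict(table[list(cl.FEATURE_NAMES)].to_numpy()) == table["state"])
            assert acc == 1.0

    def test_same_seed_same_predictions(self, training_table):
        X = training_table[list(cl.FEATURE_NAMES)].to_numpy()
        m1 = cl.train_classifier(training_table, "rf", seed=5)
        m2 = cl.train_classifier(training_table, "rf", seed=5)
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_single_class_rejected(self):
        rng = np.random.default_rng(31)
        table = balanced_random_table(rng).query("state == 'WALK'")
        with pytest.raises(ValueError, match="2 classes"):
            cl.train_classifier(table, "rf", 0)

    def test_label_permutation_gives_chance_level(self):
        """Permuted labels on balanced 5-class data: accuracy ~ 1/5."""
        rng = np.random.default_rng(32)
        accs = []
        for rep in range(10):
            table = balanced_random_table(rng, n_per_class=60)
            table["state"] = rng.permutation(table["state"].to_numpy())
            rep_acc = cl.evaluate_random_split(table, 0.25, "rf", seed=rep).accuracy
            accs.append(rep_acc)
        assert abs(np.mean(accs) - 0.2) < 0.05


class TestValidationSchemes:
    def test_random_split_high_accuracy_on_benchmark(self, training_table):
        report = cl.evaluate_random_split(training_table, kind="rf", seed=17)
        assert report.accuracy >= 0.90
        # occupied confusion rows are normalized
        sums = report.confusion.sum(axis=1, skipna=True)
        occupied = report.counts.sum(axis=1) > 0
        assert np.allclose(sums[occupied], 1.0, atol=1e-9)

    def test_zero_test_fraction_rejected(self, training_table):
        with pytest.raises(ValueError, match="test_fraction"):
            cl.evaluate_random_split(training_table, 0.0, "rf", 0)

    def test_audit_bias_makes_random_split_optimistic(self, biased_training_table):
        rand = cl.evaluate_random_split(biased_training_table, kind="rf", seed=17)
        audit = cl.evaluate_leave_one_audit_out(biased_training_table, kind="rf", seed=17)
        assert audit.accuracy <= rand.accuracy
        assert audit.accuracy < 0.99  # the bias genuinely hurts held-out audits

    def test_single_audit_rejected(self, training_table):
        one = training_table[training_table["audit"] == training_table["audit"].iloc[0]]
        with pytest.raises(ValueError, match="audit"):
            cl.evaluate_leave_one_audit_out(one, "rf", 0)

    def test_individual_folds_and_rotation_sensitivity(self):
        """A collar rotated on one individual hurts only that fold."""
        audits, traces = ht.make_training_fixture(n_individuals=3, seed=23)
        rot = traces["H02"]
        rot.samples = rot.samples[:, [1, 0, 2]]  # swap surge and sway
        table = cl.build_training_table(audits, traces)
        report = cl.evaluate_leave_one_individual_out(table, "rf", seed=0)
        per_ind = {
            ind: np.mean(
                cl.train_classifier(table[table["individual"] != ind], "rf", 0).predict(
                    table.loc[table["individual"] == ind, list(cl.FEATURE_NAMES)].to_numpy()
                )
                == table.loc[table["individual"] == ind, "state"]
            )
            for ind in ("H00", "H01", "H02")
        }
        assert per_ind["H02"] < min(per_ind["H00"], per_ind["H01"])
        assert 0.0 < report.accuracy < 1.0


class TestPrediction:
    def test_prediction_count_and_dominant_state(self, training_table):
        model = cl.train_classifier(training_table, "rf", seed=17)
        seq = ht.BehaviorSequence("H09", "2017-01-01", ["LYING"] * 200)
        trace = ht.generate_accel_trace(seq, rate=25, seed=77)
        pred = cl.predict_sequence(model, trace)
        assert pred.n == 200
        assert np.mean(pred.states == "LYING") >= 0.95

    def test_composition_rows_sum_to_one(self):
        rng = np.random.default_rng(40)
        seq = ht.BehaviorSequence(
            "x", "2017-01-01", rng.choice(ht.STATES, 300), validate=False
        )
        labels = rng.choice(["low", "medium", "high"], 300)
        comp = cl.activity_level_composition(seq, labels)
        assert np.allclose(comp.sum(axis=1), 1.0)

    def test_composition_pure_level(self):
        seq = ht.BehaviorSequence("x", "2017-01-01", ["LOPE"] * 10)
        comp = cl.activity_level_composition(seq, ["high"] * 10)
        assert comp.loc["high"].tolist() == [0.0, 1.0, 0.0, 0.0, 0.0]

    def test_misaligned_levels_rejected(self):
        seq = ht.BehaviorSequence("x", "2017-01-01", ["LOPE"] * 10)
        with pytest.raises(ValueError, match="align"):
            cl.activity_level_composition(seq, ["high"] * 9)
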