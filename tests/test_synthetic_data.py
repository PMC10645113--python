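"""Generator correctness: determinism, latent structure, rendering, IO."""

import numpy as np
import pandas as pd
import pytest

import hyenatrack as ht
from hyenatrack import activity as act
from hyenatrack.synchrony import proximity_fraction
from hyenatrack.synthetic_data import (
    DEFAULT_SIGNATURES,
    StateSignature,
    dataset_checksum,
    validate_signatures,
    write_fixture_dataset,
)
from hyenatrack.vedba import compute_vedba


class TestConfigValidation:
    def test_asymmetric_coupling_rejected(self):
        C = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ht.PopulationConfig(n_individuals=2, n_days=2, coupling_matrix=C)

    def test_single_day_rejected(self):
        with pytest.raises(ValueError, match="n_days"):
            ht.PopulationConfig(n_individuals=2, n_days=1)

    def test_bad_diagonal_rejected(self):
        C = np.array([[0.9, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="diagonal"):
            ht.PopulationConfig(n_individuals=2, n_days=2, coupling_matrix=C)


class TestLatentStructure:
    def test_determinism_across_runs(self):
        cfg = ht.PopulationConfig(n_individuals=2, n_days=2, seed=5)
        a = ht.generate_state_sequences(cfg)
        b = ht.generate_state_sequences(ht.PopulationConfig(n_individuals=2, n_days=2, seed=5))
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.states, sb.states)

    def test_adding_individual_preserves_existing_streams(self):
        cfg2 = ht.PopulationConfig(n_individuals=2, n_days=2, seed=5)
        cfg3 = ht.PopulationConfig(n_individuals=3, n_days=2, seed=5)
        a = ht.generate_state_sequences(cfg2)
        b = ht.generate_state_sequences(cfg3)
        for i in range(2):
            assert np.array_equal(a[i].states, b[i].states)

    def test_flat_null_gives_equal_hourly_expectation(self):
        cfg = ht.PopulationConfig(
            n_individuals=3,
            n_days=3,
            seed=1,
            rhythm_amplitude=0.0,
            idiosyncrasy_sd=0.0,
            latent_sd=0.0,
            day_effect_sd=0.0,
        )
        p = ht.hourly_activity_probabilities(cfg)
        assert np.allclose(p, p[0, 0])

    def test_perfect_coupling_duplicates_hourly_expectation(self):
        C = np.array([[1.0, 1.0], [1.0, 1.0]])
        cfg = ht.PopulationConfig(
            n_individuals=2, n_days=4, seed=2, coupling_matrix=C, idiosyncrasy_sd=0.0
        )
        p = ht.hourly_activity_probabilities(cfg)
        assert np.allclose(p[0], p[1], atol=1e-9)

    def test_rhythm_amplitude_raises_peak_activity(self):
        def peak_prob(amp):
            cfg = ht.PopulationConfig(
                n_individuals=1, n_days=2, seed=3, rhythm_amplitude=amp,
                idiosyncrasy_sd=0.0, latent_sd=0.0, day_effect_sd=0.0,
            )
            p = ht.hourly_activity_probabilities(cfg)
            return p[0, 19]  # evening peak hour

        assert peak_prob(0.9) > peak_prob(0.5) > peak_prob(0.1)

    def test_day_autocorr_recovered_from_daily_fractions(self):
        """Lag-1 autocorrelation of realized daily activity tracks the
        configured AR(1) coefficient (sample-autocorrelation oracle)."""
        target = -0.6
        acfs = []
        for r in range(20):
            cfg = ht.PopulationConfig(
                n_individuals=1, n_days=200, seed=100 + r, day_autocorr=target,
                day_effect_sd=0.25, latent_sd=0.0, idiosyncrasy_sd=0.0,
                persistence=0.9,
            )
            seq = ht.generate_state_sequences(cfg)[0]
            v = act.daily_activity_series(seq, utc_offset_h=0).values
            v = v - v.mean()
            acfs.append(np.sum(v[1:] * v[:-1]) / np.sum(v * v))
        assert abs(np.mean(acfs) - target) < 0.06


class TestAccelRendering:
    def test_static_noise_free_state_renders_gravity_exactly(self):
        sigs = dict(DEFAULT_SIGNATURES)
        sigs["LYING"] = StateSignature(
            "LYING", sigs["LYING"].gravity_orientation, (0.0, 0.0, 0.0), 0.0, 0.0
        )
        seq = ht.BehaviorSequence("x", "2017-01-01", ["LYING"] * 5)
        trace = ht.generate_accel_trace(seq, sigs, rate=25, seed=0)
        expected = np.asarray(sigs["LYING"].gravity_orientation)
        assert np.allclose(trace.samples, expected[None, :])

    def test_window_sample_count_at_25_hz(self):
        seq = ht.BehaviorSequence("x", "2017-01-01", ["WALK"])
        trace = ht.generate_accel_trace(seq, rate=25, seed=0)
        assert trace.n == 75

    def test_lope_window_vedba_exceeds_lying(self):
        seq = ht.BehaviorSequence("x", "2017-01-01", ["LOPE"] * 10 + ["LYING"] * 10)
        trace = ht.generate_accel_trace(seq, rate=25, seed=1)
        v = compute_vedba(trace).values
        spw = 75
        lope = v[: 10 * spw].reshape(10, spw).mean(axis=1)
        lying = v[10 * spw :].reshape(10, spw).mean(axis=1)
        assert lope.min() > lying.max()

    def test_unknown_state_rejected(self):
        seq = ht.BehaviorSequence("x", "2017-01-01", ["WALK"])
        with pytest.raises(ValueError, match="signature"):
            ht.generate_accel_trace(seq, {"LOPE": DEFAULT_SIGNATURES["LOPE"]}, 25, 0)

    def test_signature_ordering_invariant_enforced(self):
        sigs = dict(DEFAULT_SIGNATURES)
        sigs["WALK"] = StateSignature("WALK", (0.0, 0.0, 1.0), (0.2, 0.2, 0.2), 1.5, 0.01)
        with pytest.raises(ValueError, match="LOPE"):
            validate_signatures(sigs)


class TestGpsTracks:
    def test_cohoused_zero_ranging_always_proximate(self):
        cfg = ht.PopulationConfig(n_individuals=2, n_days=2, seed=6, ranging_sd=0.0)
        seqs = ht.generate_state_sequences(cfg)
        tracks = ht.generate_gps_tracks(seqs, cfg)
        assert proximity_fraction(tracks[0], tracks[1], 1.0) == 1.0

    def test_distant_home_ranges_never_proximate(self):
        cfg = ht.PopulationConfig(
            n_individuals=2, n_days=2, seed=7, ranging_sd=100.0,
            home_centers=np.array([[0.0, 0.0], [10000.0, 0.0]]),
        )
        seqs = ht.generate_state_sequences(cfg)
        tracks = ht.generate_gps_tracks(seqs, cfg)
        assert proximity_fraction(tracks[0], tracks[1], 500.0) == 0.0

    def test_proximity_increases_with_coupling(self):
        fracs = []
        for c in np.linspace(0.0, 1.0, 5):
            vals = []
            for r in range(3):
                C = np.array([[1.0, c], [c, 1.0]])
                cfg = ht.PopulationConfig(
                    n_individuals=2, n_days=2, seed=40 + r, coupling_matrix=C
                )
                seqs = ht.generate_state_sequences(cfg)
                tracks = ht.generate_gps_tracks(seqs, cfg)
                vals.append(proximity_fraction(tracks[0], tracks[1], 200.0))
            fracs.append(np.mean(vals))
        assert fracs[-1] > fracs[0]
        assert np.corrcoef(np.linspace(0, 1, 5), fracs)[0, 1] > 0.8


class TestFixtureDataset:
    def test_rerun_is_byte_identical(self, tmp_path):
        cfg = ht.PopulationConfig(n_individuals=2, n_days=2, sample_rate=1.0, seed=17)
        write_fixture_dataset(tmp_path / "a", cfg)
        write_fixture_dataset(tmp_path / "b", cfg)
        assert dataset_checksum(tmp_path / "a") == dataset_checksum(tmp_path / "b")

    def test_one_audit_file_per_individual(self, tmp_path):
        cfg = ht.PopulationConfig(n_individuals=5, n_days=2, sample_rate=1.0, seed=3)
        write_fixture_dataset(tmp_path / "d", cfg)
        audits = list((tmp_path / "d").glob("*_audit.tsv"))
        assert len(audits) == 5

    def test_accel_row_count_matches_duration(self, tmp_path):
        import pandas as pd

        cfg = ht.PopulationConfig(n_individuals=1, n_days=2, sample_rate=5.0, seed=4)
        files = write_fixture_dataset(tmp_path / "d", cfg)
        df = pd.read_csv(tmp_path / "d" / files["H00"]["accel"])
        assert len(df) == 2 * 86400 * 5

    def test_roundtrip_through_readers(self, tmp_path):
        from hyenatrack.preprocess import read_accel_csv, read_audit, read_gps_csv

        cfg = ht.PopulationConfig(n_individuals=1, n_days=2, sample_rate=1.0, seed=9)
        files = write_fixture_dataset(tmp_path / "d", cfg)
        trace = read_accel_csv(tmp_path / "d" / files["H00"]["accel"], "H00")
        assert trace.rate == 1.0
        assert trace.n == 2 * 86400
        track = read_gps_csv(tmp_path / "d" / files["H00"]["gps"], "H00")
        assert track.n == 2 * 86400
        audit = read_audit(
            tmp_path / "d" / files["H00"]["audit"], "H00", trace_start=trace.start_time
        )
        assert audit.intervals["start_s"].iloc[0] == 0.0
        assert audit.intervals["stop_s"].iloc[-1] == 2 * 86400.0
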