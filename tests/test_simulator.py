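import numpy as np
import pytest

from calibmc.session_io import read_manifest, read_session
from calibmc.simulator import (
    GLUCOSE_CENTER,
    SWEAT_BASELINE,
    SimulationConfig,
    SubjectProfile,
    SweatEventSpec,
    exact_population_model,
    generate_dataset,
    make_profiles,
    simulate_channels,
    simulate_glucose,
    simulate_rbg,
    simulate_sessions,
    simulate_sweat_signal,
)

HOUR = 3600.0
EQUIL = 75 * 60.0


def _profile(gains, kappa, noise=0.0, offset=0.0, sd=0.0):
    gains = np.asarray(gains, float)
    return SubjectProfile(
        "p", offset, sd, gains, np.asarray(kappa, float),
        np.full(gains.size, noise),
    )


class TestGlucoseProfile:
    def test_euglycaemic_plateau_before_equilibration(self):
        g = simulate_glucose(8 * HOUR, 20.0, EQUIL, seed=4)
        t = np.arange(g.size) * 20.0
        pre = g[t < EQUIL]
        assert np.all(pre == pre[0])
        assert 90 <= pre[0] <= 140

    def test_zero_amplitude_gives_constant_profile(self):
        g = simulate_glucose(8 * HOUR, 20.0, EQUIL, seed=4, amplitude=0.0)
        assert np.ptp(g) == 0.0

    def test_bounded_and_deterministic(self):
        g1 = simulate_glucose(8 * HOUR, 20.0, EQUIL, seed=9)
        g2 = simulate_glucose(8 * HOUR, 20.0, EQUIL, seed=9)
        assert np.array_equal(g1, g2)
        assert g1.min() >= 40 and g1.max() <= 400

    def test_equilibration_must_precede_end(self):
        with pytest.raises(ValueError):
            simulate_glucose(EQUIL, 20.0, EQUIL, seed=0)


class TestChannels:
    def test_pure_glucose_channel_is_centred_glucose(self):
        g = simulate_glucose(4 * HOUR, 20.0, EQUIL, seed=1)
        X, sweat_idx = simulate_channels(
            g, _profile([1.0], [0.0]), [], 20.0, seed=0, b_true=0.0, drift_sd=0.0
        )
        assert sweat_idx == -1
        np.testing.assert_allclose(X[0], g - GLUCOSE_CENTER)

    def test_persistent_offset_survives_the_event(self):
        g = np.full(1440, 100.0)
        ev = SweatEventSpec(
            onset_s=3600.0, rise_duration_s=120.0, decay_duration_s=300.0,
            amplitude=5.0, persistent_offset=1.5,
        )
        X, sweat_idx = simulate_channels(
            g, _profile([0.0, 1.0], [-1.0, 0.0]), [ev], 20.0, seed=0,
            b_true=0.0, drift_sd=0.0,
        )
        assert sweat_idx == 0
        assert X[0, 0] == pytest.approx(SWEAT_BASELINE)
        assert X[0, -1] - X[0, 0] == pytest.approx(1.5, abs=1e-6)

    def test_event_outside_grid_rejected(self):
        ev = SweatEventSpec(9e9, 60.0, 600.0, 5.0)
        with pytest.raises(ValueError, match="outside grid"):
            simulate_sweat_signal(np.arange(100) * 20.0, [ev])

    def test_leakage_raises_sweat_glucose_correlation(self):
        """Correlation between sweat and glucose channels grows with κ."""
        g = simulate_glucose(8 * HOUR, 20.0, EQUIL, seed=2)
        ev = SweatEventSpec(10_000.0, 120.0, 900.0, 6.0)

        def mean_corr(kappa):
            cs = []
            for seed in range(5):
                X, _ = simulate_channels(
                    g, _profile([0.0, 1.0], [-1.0, kappa], noise=0.05),
                    [ev], 20.0, seed=seed, b_true=0.0, drift_sd=0.0,
                )
                cs.append(np.corrcoef(X[0], X[1])[0, 1])
            return np.mean(cs)

        assert mean_corr(0.0) < mean_corr(0.1) < mean_corr(0.5)


class TestRBGSampling:
    def test_noise_free_samples_equal_truth(self):
        g = simulate_glucose(8 * HOUR, 20.0, EQUIL, seed=3)
        times, values = simulate_rbg(g, 20.0, (600, 1200), 0.0, seed=5)
        idx = np.rint(times / 20.0).astype(int)
        np.testing.assert_array_equal(values, g[idx])

    def test_fixed_gap_count(self):
        """15-min fixed gaps on an 8 h session: first RBG at t=0, then 31 more."""
        g = np.full(1440, 100.0)
        times, _ = simulate_rbg(g, 20.0, (900, 900), 0.0, seed=0)
        assert times.size == 32
        np.testing.assert_allclose(np.diff(times), 900.0)

    def test_deterministic(self):
        g = np.full(1440, 100.0)
        a = simulate_rbg(g, 20.0, (600, 1200), 0.02, seed=8)
        b = simulate_rbg(g, 20.0, (600, 1200), 0.02, seed=8)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_interval_must_fit_session(self):
        with pytest.raises(ValueError):
            simulate_rbg(np.full(100, 100.0), 20.0, (0.0, 900.0), 0.0, seed=0)


class TestDataset:
    def test_small_study_structure(self, small_config, small_dataset):
        sessions, truths, profiles = small_dataset
        assert len(sessions) == small_config.n_sessions
        counts = {}
        for s in sessions:
            counts[s.subject_id] = counts.get(s.subject_id, 0) + 1
        assert max(counts.values()) - min(counts.values()) <= 1
        for s, tr in zip(sessions, truths):
            s.validate()
            assert tr.session_id == s.session_id
            assert len(tr.events) >= 0

    def test_subject_baselines_span_configured_range(self, small_dataset):
        _, _, profiles = small_dataset
        offsets = [p.baseline_offset for p in profiles]
        assert min(offsets) == -25.0 and max(offsets) == 25.0

    def test_default_study_writes_45_sessions(self, tmp_path):
        cfg = SimulationConfig(
            n_channels=5, n_glucose_channels=2, sweat_channel=1, seed=2
        )
        manifest = generate_dataset(cfg, tmp_path)
        assert len(manifest.entries) == 45
        on_disk = read_manifest(tmp_path / "manifest.csv")
        assert len(on_disk.entries) == 45
        assert {e.split for e in on_disk.entries} == {"part1", "part2"}
        e0 = on_disk.entries[0]
        s = read_session(
            tmp_path / e0.session_file, tmp_path / e0.rbg_file,
            e0.session_id, e0.subject_id,
        )
        assert s.n_samples == 1440 and s.n_channels == 5

    def test_two_sessions_one_subject(self):
        cfg = SimulationConfig(
            n_subjects=1, n_sessions=2, n_channels=4, n_glucose_channels=1,
            sweat_channel=1, seed=3,
        )
        sessions, _, _ = simulate_sessions(cfg)
        assert {s.subject_id for s in sessions} == {"subj01"}

    def test_regeneration_is_byte_identical(self, tmp_path):
        cfg = SimulationConfig(
            n_sessions=4, n_subjects=2, n_channels=5, n_glucose_channels=2,
            sweat_channel=1, seed=6,
        )
        generate_dataset(cfg, tmp_path / "a")
        generate_dataset(cfg, tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


class TestExactRecoverability:
    def test_noiseless_generative_model_is_linear(self):
        """With κ leakage compensable and zero noise, beta·x + c reproduces
        the baseline-shifted glucose to machine precision."""
        cfg = SimulationConfig(
            n_sessions=2, n_subjects=2, n_channels=8, n_glucose_channels=3,
            sweat_channel=2, channel_noise_sd=0.0, drift_sd=0.0,
            rbg_noise_cv=0.0, seed=13,
        )
        sessions, truths, profiles = simulate_sessions(cfg)
        model = exact_population_model(profiles[0])
        for s, tr in zip(sessions, truths):
            pred = model.beta @ s.X + model.intercept
            np.testing.assert_allclose(
                pred, tr.true_glucose + tr.b_true, atol=1e-8
            )
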