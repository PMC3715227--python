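import numpy as np
import pytest
from hypothesis import given, strategies as st

from calibmc.calibration_schemes import single_baseline_plan
from calibmc.glucose_model import (
    CalibrationPlan,
    RegressionModel,
    apply_calibration,
    compute_baseline,
    fit_model,
    predict_uncalibrated,
)
from calibmc.metrics import session_accuracy
from calibmc.session_io import Session
from calibmc.simulator import SimulationConfig, simulate_sessions

from conftest import constant_model, split_by_subject, toy_session


def _ista_lasso(X, y, alpha, n_iter=20_000):
    """Independent proximal-gradient LASSO oracle on (1/2n)||y-Xw||² + α||w||₁."""
    n = X.shape[0]
    L = np.linalg.eigvalsh(X.T @ X / n).max()
    w = np.zeros(X.shape[1])
    for _ in range(n_iter):
        grad = X.T @ (X @ w - y) / n
        z = w - grad / L
        w = np.sign(z) * np.maximum(np.abs(z) - alpha / L, 0.0)
    return w


def _linear_sessions(beta_true, n_sessions=4, n_rbg=40, noise=0.0, seed=0):
    """Toy sessions whose RBG is an exact linear function of the channels,
    plus a per-session additive baseline (what calibration absorbs)."""
    rng = np.random.default_rng(seed)
    C = beta_true.size
    sessions = []
    n = 600
    t = np.arange(n) * 20.0
    for k in range(n_sessions):
        X = rng.standard_normal((C, n)).cumsum(axis=1) / 10  # smooth-ish
        offset = rng.uniform(-20, 20)
        rbg_idx = np.sort(rng.choice(n, n_rbg, replace=False))
        g = beta_true @ X[:, rbg_idx] + 120.0 - offset
        g = g + rng.normal(0, noise, n_rbg)
        g = np.maximum(g, 1.0)
        sessions.append(
            Session(f"lin{k}", f"subj{k % 2}", t, X, t[rbg_idx], g)
        )
    return sessions


class TestPrediction:
    def test_matches_hand_computed_dot_product(self):
        s = toy_session([20.0], [100.0], n_channels=2, duration_s=60.0)
        s.X[:] = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]
        model = RegressionModel([2.0, -1.0], 10.0, 0.0, 2)
        np.testing.assert_allclose(
            predict_uncalibrated(model, s), [2 - 4 + 10, 4 - 5 + 10, 6 - 6 + 10]
        )

    def test_zero_beta_returns_intercept(self):
        s = toy_session([4500.0], [100.0], n_channels=3, fill=7.0)
        model = constant_model(3, intercept=42.0)
        assert np.all(predict_uncalibrated(model, s) == 42.0)

    def test_linearity_in_a_channel(self):
        s = toy_session([4500.0], [100.0], n_channels=2, fill=1.0)
        model = RegressionModel([1.0, 0.5], 0.0, 0.0, 2)
        base = predict_uncalibrated(model, s).copy()
        s.X[0] += 3.0
        np.testing.assert_allclose(predict_uncalibrated(model, s), base + 3.0)

    def test_channel_mismatch_rejected(self):
        s = toy_session([4500.0], [100.0], n_channels=2)
        with pytest.raises(ValueError, match="channels"):
            predict_uncalibrated(constant_model(3), s)


class TestFit:
    def test_huge_lambda_shrinks_all_coefficients_to_zero(self):
        sessions = _linear_sessions(np.array([1.0, -2.0, 0.0]), seed=1)
        model = fit_model(sessions, lambda_grid=[1e6], cv_folds=2)
        assert np.all(model.beta == 0.0)
        s = sessions[0]
        assert np.all(predict_uncalibrated(model, s) == model.intercept)

    def test_support_recovery_matches_ista_oracle(self):
        """3 active of 20 channels, moderate noise: the coordinate-descent
        fit agrees with an independent proximal-gradient solver and puts the
        active channels far above the inactive ones."""
        beta_true = np.zeros(20)
        beta_true[[2, 7, 15]] = [3.0, -2.0, 1.5]
        sessions = _linear_sessions(beta_true, n_sessions=6, noise=1.0, seed=4)
        lam = 0.2
        model = fit_model(sessions, lambda_grid=[lam], cv_folds=2)
        # oracle on the identical pooled, within-session-centred design
        Xc, yc = [], []
        for s in sessions:
            idx = s.nearest_index(s.rbg_times)
            x = s.X[:, idx].T
            Xc.append(x - x.mean(axis=0))
            yc.append(s.rbg_values - s.rbg_values.mean())
        X = np.vstack(Xc)
        scale = X.std(axis=0)
        w = _ista_lasso(X / scale, np.concatenate(yc), lam) / scale
        np.testing.assert_allclose(model.beta, w, atol=1e-4)
        active = np.abs(model.beta[[2, 7, 15]])
        inactive = np.abs(np.delete(model.beta, [2, 7, 15]))
        assert active.min() > 10 * max(inactive.max(), 1e-12)

    def test_degenerate_and_empty_inputs_rejected(self):
        flat = [
            toy_session([4500.0, 9000.0], [100.0, 110.0], session_id=f"f{k}")
            for k in range(2)
        ]
        with pytest.raises(ValueError, match="degenerate"):
            fit_model(flat)
        ok = _linear_sessions(np.array([1.0]), n_sessions=2)
        with pytest.raises(ValueError, match="lambda_grid"):
            fit_model(ok, lambda_grid=[])
        with pytest.raises(ValueError, match="2 identification"):
            fit_model(ok[:1])

    def test_deterministic_given_seed(self):
        sessions = _linear_sessions(np.array([1.0, 0.0, -1.0]), noise=0.5, seed=2)
        m1 = fit_model(sessions, seed=5)
        m2 = fit_model(sessions, seed=5)
        assert np.array_equal(m1.beta, m2.beta) and m1.lam == m2.lam


class TestBaseline:
    def test_baseline_is_model_minus_reference(self):
        s = toy_session([4500.0], [100.0], n_channels=1, fill=0.0)
        model = constant_model(1, intercept=120.0)
        assert compute_baseline(model, s, 4500.0) == pytest.approx(20.0)

    def test_perfect_model_gives_zero_baseline(self):
        s = toy_session([4500.0], [120.0], n_channels=1)
        model = constant_model(1, intercept=120.0)
        assert compute_baseline(model, s, 4500.0) == pytest.approx(0.0)

    def test_no_rbg_near_instant_rejected(self):
        s = toy_session([4500.0], [100.0])
        with pytest.raises(ValueError, match="no RBG within"):
            compute_baseline(constant_model(1), s, 20_000.0)

    @given(st.floats(-50, 50))
    def test_reference_shift_equivariance(self, c):
        """Adding c to every RBG shifts b by −c and the calibrated series by +c."""
        s = toy_session([4500.0, 9000.0], [100.0, 140.0], fill=1.0)
        model = RegressionModel([2.0], 50.0, 0.0, 1)
        s_shift = toy_session([4500.0, 9000.0], [100.0 + c, 140.0 + c], fill=1.0)
        b0 = compute_baseline(model, s, 4500.0)
        b1 = compute_baseline(model, s_shift, 4500.0)
        assert b1 == pytest.approx(b0 - c)
        g0 = apply_calibration(model, s, CalibrationPlan([4500.0], [b0]))
        g1 = apply_calibration(model, s_shift, CalibrationPlan([4500.0], [b1]))
        np.testing.assert_allclose(g1[225:], g0[225:] + c)


class TestCalibration:
    def test_calibrated_series_passes_through_the_reference(self, small_dataset, small_model):
        sessions, _, _ = small_dataset
        for s in sessions[:4]:
            plan = single_baseline_plan(small_model, s)
            cal = apply_calibration(small_model, s, plan)
            idx = s.nearest_index(plan.times[0])
            k = np.argmin(np.abs(s.rbg_times - plan.times[0]))
            assert cal[idx] == pytest.approx(s.rbg_values[k])

    def test_undefined_before_first_calibration(self):
        s = toy_session([4500.0], [100.0], fill=1.0)
        cal = apply_calibration(
            constant_model(1, 100.0), s, CalibrationPlan([4500.0], [0.0])
        )
        assert np.all(np.isnan(cal[s.t < 4500.0 - s.dt]))
        assert np.all(np.isfinite(cal[s.t >= 4500.0]))

    def test_two_entry_plan_is_piecewise_shifted(self):
        s = toy_session([4500.0, 18_000.0], [100.0, 100.0], fill=0.0)
        model = constant_model(1, 100.0)
        cal = apply_calibration(
            model, s, CalibrationPlan([4500.0, 18_000.0], [10.0, -5.0])
        )
        assert cal[s.nearest_index(5000.0)] == pytest.approx(90.0)
        assert cal[s.nearest_index(20_000.0)] == pytest.approx(105.0)

    def test_noiseless_pipeline_reproduces_truth(self):
        """κ = 0, zero-noise study: identification + single-baseline
        calibration reproduce true glucose on held-out sessions."""
        cfg = SimulationConfig(
            n_sessions=8, n_subjects=4, n_channels=10, n_glucose_channels=4,
            sweat_channel=2, channel_noise_sd=0.0, drift_sd=0.0,
            rbg_noise_cv=0.0, sweat_leakage_scale=0.0, seed=21,
        )
        sessions, truths, _ = simulate_sessions(cfg)
        ident, test = split_by_subject(sessions, seed=1)
        model = fit_model(ident, seed=0)
        truth = {t.session_id: t for t in truths}
        for s in test:
            plan = single_baseline_plan(model, s)
            cal = apply_calibration(model, s, plan)
            mask = s.t >= plan.t0
            err = cal[mask] - truth[s.session_id].true_glucose[mask]
            assert np.sqrt(np.mean(err**2)) < 0.5
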