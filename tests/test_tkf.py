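"""Tobit Kalman filter: thresholds, censoring, update equations, and the
KF-equivalence limit against an independently implemented linear filter."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import motionmend as mm
from motionmend.tkf import (TKFConfig, TKFState, Thresholds, _kf_update,
                            windowed_vmax)

WIDE = Thresholds(np.full(3, -1e9), np.full(3, 1e9))


def linear_kf_oracle(measured, config):
    """Textbook linear Kalman filter, written independently of the package
    internals (explicit inverse, no censoring machinery)."""
    dt = config.dt
    F = np.eye(6)
    for i in range(3):
        F[i, i + 3] = dt
    H = np.zeros((3, 6))
    H[0, 0] = H[1, 1] = H[2, 2] = 1.0
    Q = config.process_noise()
    R = config.measurement_noise()
    x = np.zeros(6)
    x[:3] = measured[0]
    x[3:] = (measured[1] - measured[0]) / dt
    P = config.initial_covariance().copy()
    out = np.empty_like(measured)
    out[0] = measured[0]
    for k in range(1, len(measured)):
        x = F @ x
        P = F @ P @ F.T + Q
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        x = x + K @ (measured[k] - H @ x)
        P = (np.eye(6) - K @ H) @ P
        out[k] = x[:3]
    return out


class TestThresholds:
    def test_substitution_example(self):
        # prev 10, |v_max| 2 cm/s, dt 0.5 s -> (9, 11)
        cfg = TKFConfig(dt=0.5, window_frames=4)
        measured = np.zeros((8, 3))
        measured[:, 0] = np.arange(8)  # v = 2 cm/s at fps 2
        thr = mm.compute_thresholds(np.full(3, 10.0), measured, 4, cfg, fps=2.0)
        assert thr.t_low[0] == pytest.approx(9.0)
        assert thr.t_high[0] == pytest.approx(11.0)

    def test_zero_velocity_collapses_interval(self):
        cfg = TKFConfig(dt=0.5, window_frames=4)
        measured = np.ones((8, 3))
        thr = mm.compute_thresholds(np.full(3, 5.0), measured, 3, cfg, fps=2.0)
        np.testing.assert_array_equal(thr.t_low, thr.t_high)

    def test_window_truncated_at_start(self):
        v = windowed_vmax(np.arange(12.0)[:, None] * np.ones(3), 60.0,
                          frame_k=1, window_frames=60)
        assert np.all(np.isfinite(v))

    def test_frame_zero_rejected(self):
        with pytest.raises(ValueError):
            mm.compute_thresholds(np.zeros(3), np.zeros((5, 3)), 0, TKFConfig())


class TestCensor:
    @pytest.mark.parametrize("q,expected", [(10.0, 10.0), (8.0, 9.0), (12.0, 11.0)])
    def test_three_regions(self, q, expected):
        thr = Thresholds(np.full(3, 9.0), np.full(3, 11.0))
        assert mm.censor(np.full(3, q), thr)[0] == expected

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3), st.floats(0, 100))
    def test_output_always_within_interval(self, q, lo, width):
        thr = Thresholds(np.full(3, lo), np.full(3, lo + width))
        rho = mm.censor(np.full(3, q), thr)
        assert np.all(rho >= thr.t_low) and np.all(rho <= thr.t_high)


class TestPredict:
    def test_static_state_unchanged_with_zero_q(self):
        cfg = TKFConfig(dt=1 / 60, Q=np.zeros((6, 6)))
        s = TKFState(np.array([1.0, 2, 3, 0, 0, 0]), np.eye(6))
        out = mm.predict(s, cfg)
        np.testing.assert_array_equal(out.x[:3], [1.0, 2, 3])

    def test_cv_advance(self):
        cfg = TKFConfig(dt=1 / 60)
        s = TKFState(np.array([0.0, 0, 0, 120.0, 0, 0]), np.eye(6))
        out = mm.predict(s, cfg)
        assert out.x[0] == pytest.approx(2.0)

    def test_covariance_grows(self):
        cfg = TKFConfig(dt=1 / 60)
        s = TKFState(np.zeros(6), np.eye(6))
        out = mm.predict(s, cfg)
        assert np.trace(out.P) >= np.trace(s.P)


class TestTobitUpdate:
    def test_wide_thresholds_equal_linear_kf(self):
        rng = np.random.default_rng(0)
        cfg = TKFConfig(dt=1 / 60, sigma_r=2.0)
        for _ in range(20):
            x = rng.normal(size=6) * 10
            A = rng.normal(size=(6, 6))
            s = TKFState(x, A @ A.T + np.eye(6))
            pred = mm.predict(s, cfg)
            q = pred.x[:3] + rng.normal(size=3)
            tkf_state, probs = mm.tobit_update(pred, q, WIDE, cfg)
            kf_state = _kf_update(pred, q, cfg)
            np.testing.assert_array_equal(probs.p_uc, np.ones(3))
            np.testing.assert_allclose(tkf_state.x, kf_state.x, rtol=1e-8,
                                       atol=1e-10)
            np.testing.assert_allclose(tkf_state.P, kf_state.P, rtol=1e-8,
                                       atol=1e-12)

    def test_degenerate_interval_keeps_prior_covariance(self):
        cfg = TKFConfig(dt=1 / 60)
        pred = TKFState(np.zeros(6), np.eye(6))
        thr = Thresholds(np.ones(3), np.ones(3))  # T_L = T_H
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state, probs = mm.tobit_update(pred, np.ones(3), thr, cfg)
        np.testing.assert_array_equal(probs.p_uc, np.zeros(3))
        np.testing.assert_allclose(state.P, pred.P, atol=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(-50, 50), st.floats(0.01, 40), st.floats(-20, 20))
    def test_probabilities_partition_unity(self, lo, width, center):
        cfg = TKFConfig(dt=1 / 60)
        pred = TKFState(np.array([center] * 3 + [0.0] * 3), np.eye(6) * 4)
        thr = Thresholds(np.full(3, lo), np.full(3, lo + width))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, probs = mm.tobit_update(pred, mm.censor(np.zeros(3), thr),
                                       thr, cfg)
        np.testing.assert_allclose(probs.p_uc + probs.p_l + probs.p_h, 1.0,
                                   atol=1e-9)


class TestFilterSequence:
    def test_variance_reduction_on_static_joint(self, skel):
        rng = np.random.default_rng(1)
        pos = np.tile(skel.rest_pose, (300, 1, 1))
        seq = mm.MotionSequence(skel, 60.0, pos)
        noisy = mm.corrupt_awgn(seq, 5.0, seed=2)
        cfg = TKFConfig(dt=1 / 60, sigma_r=5.0 / np.sqrt(3), sigma_a=100.0)
        filt, _ = mm.filter_sequence(noisy, cfg)
        burn = 20
        var_f = np.var(filt.positions[burn:] - pos[burn:], axis=0).mean()
        var_m = np.var(noisy.positions[burn:] - pos[burn:], axis=0).mean()
        assert var_f < var_m

    def test_noiseless_cv_trajectory_tracked(self, skel):
        # wide fixed thresholds: the Tobit update runs in its uncensored
        # regime (an exactly CV-matched trajectory rides the adaptive
        # threshold boundary, a degenerate case documented in the methods)
        pos = np.tile(skel.rest_pose, (120, 1, 1))
        pos[:, :, 0] += 2.0 * np.arange(120)[:, None]  # 120 cm/s at 60 fps
        seq = mm.MotionSequence(skel, 60.0, pos)
        cfg = TKFConfig(dt=1 / 60, Q=np.zeros((6, 6)), sigma_r=1.0,
                        threshold_mode="fixed",
                        fixed_t_low=np.full(3, -1e9),
                        fixed_t_high=np.full(3, 1e9))
        filt, _ = mm.filter_sequence(seq, cfg)
        err = np.abs(filt.positions[20:] - pos[20:]).max()
        assert err < 1e-6

    def test_threshold_mode_none_matches_kf_oracle(self, skel):
        seq, _ = mm.generate_motion(skel, 150, 60.0, mm.GaitParams(seed=5))
        noisy = mm.corrupt_awgn(seq, 6.0, seed=6)
        cfg = TKFConfig(dt=1 / 60, sigma_r=6.0 / np.sqrt(3))
        filt, _ = mm.filter_sequence(noisy, cfg.__class__(
            dt=cfg.dt, sigma_a=cfg.sigma_a, sigma_r=cfg.sigma_r,
            threshold_mode="none"))
        for j in [0, 7, 15]:
            oracle = linear_kf_oracle(noisy.positions[:, j, :], cfg)
            np.testing.assert_allclose(filt.positions[:, j, :], oracle,
                                       rtol=1e-8, atol=1e-8)

    def test_masked_frames_are_prediction_only(self, skel):
        seq, _ = mm.generate_motion(skel, 100, 60.0, mm.GaitParams(seed=7))
        holes = mm.corrupt_dropout(seq, 0.3, seed=8)
        filt, diag = mm.filter_sequence(holes, TKFConfig(dt=1 / 60))
        # masked frames carry zero uncensored probability in the diagnostics
        m = ~holes.mask[1:, :]
        assert np.all(diag["p_uc"][1:][m] == 0.0)
        assert np.isfinite(filt.positions).all()

    def test_mirrored_input_mirrors_output(self, skel):
        seq, _ = mm.generate_motion(skel, 120, 60.0, mm.GaitParams(seed=9))
        noisy = mm.corrupt_awgn(seq, 4.0, seed=10)
        mirrored = noisy.copy()
        mirrored.positions[:, :, 0] *= -1
        cfg = TKFConfig(dt=1 / 60, sigma_r=4.0 / np.sqrt(3))
        a, _ = mm.filter_sequence(noisy, cfg)
        b, _ = mm.filter_sequence(mirrored, cfg)
        np.testing.assert_allclose(b.positions[:, :, 0],
                                   -a.positions[:, :, 0], atol=1e-9)
        np.testing.assert_allclose(b.positions[:, :, 1:],
                                   a.positions[:, :, 1:], atol=1e-9)

    def test_tkf_beats_kf_under_occlusion_bursts(self, skel):
        """Sustained occlusion bias is resisted by censoring (causal window)
        but accepted by the plain KF."""
        seq, _ = mm.generate_motion(skel, 480, 60.0, mm.GaitParams(seed=2))
        spec = mm.CorruptionSpec(mode="dmocap_like", sigma_cm=2.0,
                                 burst_rate=1.0, burst_length=60,
                                 burst_bias_cm=20.0, outlier_rate=0.002,
                                 seed=3)
        cor, _ = mm.corrupt_dmocap_like(seq, spec)
        kf_cfg = TKFConfig(dt=1 / 60, sigma_r=3.0, threshold_mode="none")
        tkf_cfg = TKFConfig(dt=1 / 60, sigma_r=3.0, threshold_mode="adaptive",
                            causal=True)
        kf_out, _ = mm.filter_sequence(cor, kf_cfg)
        tkf_out, _ = mm.filter_sequence(cor, tkf_cfg)
        assert mm.joint_rmse(tkf_out, seq)[1] < mm.joint_rmse(kf_out, seq)[1]

    def test_estimator_wrapper(self, skel):
        seq, _ = mm.generate_motion(skel, 80, 60.0, mm.GaitParams(seed=11))
        est = mm.TobitKalmanFilter(sigma_r=2.0)
        out = est.fit().transform(seq)
        assert out.positions.shape == seq.positions.shape
        assert "p_uc" in est.diagnostics_
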