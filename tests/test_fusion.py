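"""Complementary-filter fusion: tilt, drift correction, joint angle, envelopes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import imuwrist as iw
from imuwrist.errors import (
    ConfigError,
    InvalidParameterError,
    SampleCountError,
    UndefinedTiltError,
)
from imuwrist.fusion import DriftConfig, DriftEstimate, estimate_drift


class TestAccelTilt:
    @pytest.mark.parametrize("ax,az,expected", [
        (0.0, 1.0, 0.0),        # gravity along Z: neutral posture
        (1.0, 0.0, 90.0),       # quarter rotation
        (0.5, 0.8660254, 30.0),
        (0.0, -1.0, 180.0),     # inverted: boundary maps to +180
    ])
    def test_known_angles(self, ax, az, expected):
        assert iw.accel_tilt(ax, az) == pytest.approx(expected, abs=1e-5)

    def test_zero_vector_rejected(self):
        with pytest.raises(UndefinedTiltError):
            iw.accel_tilt(0.0, 0.0)

    @given(st.floats(-179.999, 180.0))
    @settings(max_examples=50, deadline=None)
    def test_recovers_angle_of_unit_gravity(self, angle):
        ax = np.sin(np.radians(angle))
        az = np.cos(np.radians(angle))
        got = iw.accel_tilt(ax, az)
        assert -180.0 < got <= 180.0
        assert got == pytest.approx(angle, abs=1e-6)


class TestStaticDrift:
    def test_constant_series_recovered(self):
        gyro = np.full(1000, 0.7)
        assert iw.estimate_static_drift(gyro) == pytest.approx(0.7)

    def test_bias_recovered_under_noise_within_three_se(self):
        rng = np.random.default_rng(3)
        gyro = 0.5 + rng.normal(0, 0.1, size=1500)
        cfg = DriftConfig(n=0, m=5, r=100)
        est = iw.estimate_static_drift(gyro, cfg)
        # brute-force oracle: plain mean over the same five 100-sample windows
        oracle = np.mean([gyro[j * 100:(j + 1) * 100] for j in range(5)])
        assert est == pytest.approx(oracle)
        assert abs(est - 0.5) < 3 * 0.1 / np.sqrt(500)

    def test_exact_bound_length_rejected(self):
        cfg = DriftConfig(n=0, m=5, r=100)
        with pytest.raises(SampleCountError, match="900"):
            iw.estimate_static_drift(np.zeros(cfg.min_samples), cfg)

    def test_m_of_three_unconstructible(self):
        with pytest.raises(ConfigError):
            DriftConfig(m=3)


class TestCorrectGyro:
    def test_pure_bias_removed(self):
        gyro = np.full(1200, 1.3)
        out = iw.correct_gyro(gyro)
        assert np.abs(out).max() < 1e-9

    def test_smooth_signal_preserved_through_calibration(self):
        t = np.arange(1500) / 100.0
        signal = 20 * np.sin(2 * np.pi * 0.5 * t) ** 2
        gyro = signal + 0.8
        cfg = DriftConfig()
        drift = DriftEstimate(np.asarray(0.8), None)
        out = iw.correct_gyro(gyro, drift, cfg)
        # the bias is gone and the movement signal passes within the
        # smoother's passband tolerance (~2% of the 10 deg/s component)
        assert np.abs(out - signal).max() < 0.5

    def test_even_sg_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            DriftConfig(sg_window=0)
        with pytest.raises(InvalidParameterError):
            DriftConfig(sg_window=50)

    def test_sg_window_longer_than_series_rejected(self):
        with pytest.raises(InvalidParameterError):
            iw.correct_gyro(np.zeros(1000), None, DriftConfig(sg_window=1001))

    def test_full_estimate_reports_static_and_moving_parts(self):
        gyro = np.full(1200, 0.4)
        est = estimate_drift(gyro)
        assert est.omega_bar_static == pytest.approx(0.4)
        assert est.moving_drift.shape == gyro.shape


class TestComplementaryFilter:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            iw.FusionConfig(h=0.98, l=0.05)
        with pytest.raises(ConfigError):
            iw.FusionConfig(h=1.5)

    @pytest.mark.parametrize("sigma,omega,theta,h,expected", [
        (10.0, 0.0, 10.0, 0.98, 10.0),   # fixed point
        (0.0, 5.0, 0.0, 1.0, 0.05),      # pure gyro integration, dt=0.01
        (0.0, 0.0, 42.0, 0.0, 42.0),     # pure accelerometer
    ])
    def test_single_step(self, sigma, omega, theta, h, expected):
        cfg = iw.FusionConfig(h=h, dt=0.01)
        assert iw.complementary_step(sigma, omega, theta, cfg) == pytest.approx(expected)

    @given(st.floats(0.0, 1.0), st.floats(-90, 90))
    @settings(max_examples=30, deadline=None)
    def test_agreeing_observations_are_a_fixed_point(self, h, angle):
        cfg = iw.FusionConfig(h=h, dt=0.01)
        out = iw.complementary_step(angle, 0.0, angle, cfg)
        assert out == pytest.approx(angle, abs=1e-9)


class TestTrackOrientation:
    def test_static_sensor_stays_at_zero(self, noiseless):
        n = 1200
        profile = iw.MotionProfile(t=np.arange(n) / 100.0,
                                   theta_true=np.zeros(n), omega_true=np.zeros(n))
        trial = iw.synthesize_recording(profile, noise=noiseless, seed=0)
        state = iw.track_orientation(trial.hand)
        assert np.abs(state.sigma).max() < 1e-6

    def test_converges_to_held_angle(self, long_clean_trial):
        trial, profile = long_clean_trial
        state = iw.track_orientation(trial.hand)
        hold = profile.theta_true == 70.0
        assert abs(state.sigma[hold][-1] - 70.0) < 0.5

    def test_uncorrected_biased_gyro_drifts_linearly(self):
        n = 2000
        bias = 0.8
        profile = iw.MotionProfile(t=np.arange(n) / 100.0,
                                   theta_true=np.zeros(n), omega_true=np.zeros(n))
        noise = iw.SensorNoiseModel.noiseless()
        noise.gyro_static_bias = (0.0, bias, 0.0)
        trial = iw.synthesize_recording(profile, noise=noise, seed=0)
        cfg = iw.FusionConfig(h=1.0, dt=0.01)
        state = iw.track_orientation(trial.hand, cfg, correct_drift=False)
        expected_ramp = bias * (n - 1) / 100.0
        assert state.sigma[-1] == pytest.approx(expected_ramp, rel=0.05)


class TestJointAngle:
    def test_identical_states_give_zero(self):
        s = iw.OrientationState(sigma=np.linspace(0, 50, 100))
        series = iw.joint_angle(s, s, np.arange(100) / 100.0)
        assert np.all(series.angle == 0)
        assert series.range == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a = iw.OrientationState(sigma=rng.normal(size=200))
        b = iw.OrientationState(sigma=rng.normal(size=200))
        t = np.arange(200) / 100.0
        fwd = iw.joint_angle(a, b, t)
        rev = iw.joint_angle(b, a, t)
        assert np.allclose(fwd.angle, -rev.angle)

    def test_length_mismatch_rejected(self):
        a = iw.OrientationState(sigma=np.zeros(10))
        b = iw.OrientationState(sigma=np.zeros(11))
        with pytest.raises(InvalidParameterError):
            iw.joint_angle(a, b, np.zeros(10))

    def test_recovers_stop_sign_peak(self, long_clean_trial):
        trial, _ = long_clean_trial
        trimmed = iw.trim_startup(trial, 1.0)
        series = iw.joint_angle_from_trial(trimmed)
        assert series.max_angle == pytest.approx(70.0, abs=1.0)
        assert series.range == pytest.approx(70.0, abs=1.5)


class TestPeakAngleErrorExperiment:
    def test_noise_free_error_near_zero(self, noiseless):
        err = iw.peak_angle_error_experiment(
            [30], [30, 50, 70, 90], "one-static", n_trials=8,
            noise=noiseless, seed=1,
        )
        assert abs(err) < 0.1

    def test_end_to_end_peak_recovery_within_one_degree(self, noiseless):
        # 20 seeded noise-free trials across four predetermined peaks
        for peak in (30.0, 50.0, 70.0, 90.0):
            for trial_seed in range(5):
                profile = iw.generate_stop_sign_profile(
                    duration=max(15.0, 6 + 2 * 1.2 * peak / 35 + 3),
                    peak_angle=peak, speed=35, lead_in=6.0,
                )
                trial = iw.synthesize_recording(profile, noise=noiseless,
                                                seed=trial_seed)
                series = iw.joint_angle_from_trial(iw.trim_startup(trial, 1.0))
                assert abs(series.max_angle - peak) < 1.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(InvalidParameterError):
            iw.peak_angle_error_experiment([30], [30], "sideways", n_trials=1)
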