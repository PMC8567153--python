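"""Two-sensor wrist joint-angle estimation by complementary filtering.

Each sensor's orientation on the X-Z plane is tracked by blending two
observations of the same angle:

* the accelerometer tilt ``beta = atan2(a_x, a_z)`` — drift-free but
  noisy and corrupted by linear acceleration;
* the integral of the gyroscope Y rate — smooth but drifting, so the
  rate is first corrected for its static bias (averaged over stationary
  windows) and then calibrated with a zero-phase Savitzky-Golay
  polynomial smoother.

The complementary filter combines them per sample,

    sigma[k] = h * (sigma[k-1] + omega_gf[k] * dt) + l * beta[k],

with high-pass weight ``h`` and low-pass weight ``l`` constrained to
``h + l = 1``.  Because the two sensors share a frame and zero position,
the wrist joint angle is simply the difference between the two filtered
orientations — no Euler-angle or quaternion tracking is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter, savgol_filter

from .errors import (
    ConfigError,
    InvalidParameterError,
    SampleCountError,
    UndefinedTiltError,
)
from .io import RawTrial, trim_startup
from .synth import (
    CHANNELS,
    SensorNoiseModel,
    generate_stop_sign_profile,
    synthesize_recording,
)


# ---------------------------------------------------------------------------
# accelerometer tilt

@dataclass
class TiltAngles:
    """Projected orientation angles from one accelerometer sample set.

    ``theta_zx`` (== ``beta``, the angle driving the joint measurement)
    is the gravity direction projected on the X-Z plane; ``theta_yz``
    and ``theta_zy`` are the analogous projections involving the Y axis.
    All in degrees, in (-180, 180].
    """

    theta_zx: np.ndarray
    theta_yz: np.ndarray
    theta_zy: np.ndarray

    @property
    def beta(self) -> np.ndarray:
        return self.theta_zx


def accel_tilt(a_x, a_z):
    """Four-quadrant tilt of gravity on the X-Z plane, degrees in (-180, 180].

    Accepts scalars or arrays; raises :class:`UndefinedTiltError` if any
    sample has ``a_x == a_z == 0`` (gravity orthogonal to the plane).
    """
    a_x = np.asarray(a_x, dtype=float)
    a_z = np.asarray(a_z, dtype=float)
    if np.any((a_x == 0) & (a_z == 0)):
        raise UndefinedTiltError("tilt undefined for zero (a_x, a_z) vector")
    beta = np.degrees(np.arctan2(a_x, a_z))
    beta = np.where(beta <= -180.0, beta + 360.0, beta)
    return beta if beta.ndim else float(beta)


def tilt_angles(accel: np.ndarray) -> TiltAngles:
    """All three projected tilt angles for an ``(n, 3)`` accelerometer block."""
    ax, ay, az = accel[:, 0], accel[:, 1], accel[:, 2]
    return TiltAngles(
        theta_zx=accel_tilt(ax, az),
        theta_yz=accel_tilt(ay, az),
        theta_zy=accel_tilt(az, ay),
    )


# ---------------------------------------------------------------------------
# gyroscope drift correction

@dataclass
class DriftConfig:
    """Static-window layout and smoother settings for drift correction.

    The static bias is averaged over ``m`` windows of ``window_len``
    samples, window ``j`` starting at sample ``n + j*r``; the series must
    be longer than ``n + (m-1)*r + window_len*m`` samples.  ``sg_window``
    (odd) and ``sg_order`` parameterize the Savitzky-Golay smoother that
    calibrates the bias-corrected rate.
    """

    n: int = 0
    m: int = 5
    r: int = 100
    window_len: int = 100
    sg_window: int = 51
    sg_order: int = 3

    def __post_init__(self) -> None:
        if self.n < 0 or self.r < 0:
            raise ConfigError("n and r must be >= 0")
        if self.m <= 3:
            raise ConfigError("m must be larger than 3")
        if self.window_len <= 0:
            raise ConfigError("window_len must be > 0")
        if self.sg_window <= 0 or self.sg_window % 2 == 0:
            raise InvalidParameterError("sg_window must be a positive odd integer")
        if self.sg_order >= self.sg_window:
            raise ConfigError("sg_order must be smaller than sg_window")

    @property
    def min_samples(self) -> int:
        """Series must be strictly longer than this to estimate drift."""
        return self.n + (self.m - 1) * self.r + self.window_len * self.m


@dataclass
class DriftEstimate:
    """Static gyro bias per axis plus the calibrated (smoothed) rate.

    ``omega_bar_static`` is the average static drift in deg/s;
    ``moving_drift`` is the slowly varying residual tracked by the
    Savitzky-Golay smoother after bias removal, same shape as the input
    series.
    """

    omega_bar_static: np.ndarray
    moving_drift: np.ndarray


def estimate_static_drift(gyro: np.ndarray, cfg: DriftConfig | None = None) -> np.ndarray:
    """Average static drift: the mean gyro reading over the m stationary windows.

    ``gyro`` is ``(n,)`` or ``(n, 3)`` in deg/s; returns a scalar or a
    per-axis array.  Raises :class:`SampleCountError` unless the series
    is strictly longer than ``n + (m-1)*r + window_len*m``.
    """
    cfg = cfg or DriftConfig()
    gyro = np.asarray(gyro, dtype=float)
    n_samples = gyro.shape[0]
    if n_samples <= cfg.min_samples:
        raise SampleCountError(
            f"need more than {cfg.min_samples} samples "
            f"(n + (m-1)r + {cfg.window_len}m), got {n_samples}"
        )
    chunks = [gyro[cfg.n + j * cfg.r: cfg.n + j * cfg.r + cfg.window_len]
              for j in range(cfg.m)]
    stacked = np.concatenate(chunks, axis=0)
    bias = stacked.mean(axis=0)
    return bias if gyro.ndim > 1 else float(bias)


def correct_gyro(
    gyro: np.ndarray,
    drift: DriftEstimate | None = None,
    cfg: DriftConfig | None = None,
) -> np.ndarray:
    """Drift-corrected angular rate ``omega_gf``.

    Subtracts the average static drift and calibrates the residual with
    a zero-phase Savitzky-Golay smoother, which suppresses wideband
    sensor noise (the source of random-walk drift when the rate is
    integrated) while passing the smooth movement signal unchanged.
    If ``drift`` is not supplied it is estimated from the series itself.
    """
    cfg = cfg or DriftConfig()
    gyro = np.asarray(gyro, dtype=float)
    if cfg.sg_window > gyro.shape[0]:
        raise InvalidParameterError(
            f"sg_window {cfg.sg_window} exceeds series length {gyro.shape[0]}"
        )
    bias = (drift.omega_bar_static if drift is not None
            else estimate_static_drift(gyro, cfg))
    residual = gyro - bias
    return savgol_filter(residual, cfg.sg_window, cfg.sg_order, axis=0)


def estimate_drift(gyro: np.ndarray, cfg: DriftConfig | None = None) -> DriftEstimate:
    """Full drift estimate: static bias plus the calibrated residual series."""
    cfg = cfg or DriftConfig()
    bias = estimate_static_drift(gyro, cfg)
    moving = correct_gyro(gyro, DriftEstimate(np.asarray(bias), None), cfg)
    return DriftEstimate(omega_bar_static=np.asarray(bias), moving_drift=moving)


# ---------------------------------------------------------------------------
# complementary filter

@dataclass
class FusionConfig:
    """Complementary-filter weights and timing.

    ``h`` weights the gyro-integration path, ``l`` the accelerometer
    tilt; they must sum to 1 exactly (``l`` defaults to ``1 - h``).
    ``dt`` is the sample interval in seconds.  ``init_angle`` seeds the
    filter; ``None`` means "use the first accelerometer tilt sample".
    """

    h: float = 0.98
    l: float | None = None
    dt: float = 0.01
    init_angle: float | None = None

    def __post_init__(self) -> None:
        if self.l is None:
            self.l = 1.0 - self.h
        if not 0.0 <= self.h <= 1.0:
            raise ConfigError("h must lie in [0, 1]")
        if abs(self.h + self.l - 1.0) > 1e-12:
            raise ConfigError(f"h + l must equal 1 (got {self.h + self.l!r})")
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")


@dataclass
class OrientationState:
    """Filtered orientation along the fused axis for one sensor.

    ``sigma`` is the per-sample filtered angle (degrees) on the X-Z
    plane; ``tilt`` the raw accelerometer observation it was blended
    with; ``omega_gf`` the drift-corrected gyro rate that was integrated.
    """

    sigma: np.ndarray
    tilt: np.ndarray | None = None
    omega_gf: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.sigma)


def complementary_step(sigma_prev: float, omega_gfc: float, theta_ab: float,
                       cfg: FusionConfig) -> float:
    """One filter update: ``h*(sigma_prev + omega*dt) + l*theta_ab``."""
    return cfg.h * (sigma_prev + omega_gfc * cfg.dt) + cfg.l * theta_ab


def _complementary_series(omega: np.ndarray, theta: np.ndarray,
                          cfg: FusionConfig) -> np.ndarray:
    """Vectorized filter recurrence via a first-order IIR filter."""
    sigma0 = float(theta[0] if cfg.init_angle is None else cfg.init_angle)
    u = cfg.h * omega * cfg.dt + cfg.l * theta
    # sigma[k] = u[k] + h * sigma[k-1], seeded with sigma0
    rest, _ = lfilter([1.0], [1.0, -cfg.h], u[1:], zi=[cfg.h * sigma0])
    return np.concatenate([[sigma0], rest])


def track_orientation(
    stream: np.ndarray,
    cfg: FusionConfig | None = None,
    drift_cfg: DriftConfig | None = None,
    correct_drift: bool = True,
) -> OrientationState:
    """Filtered X-Z-plane orientation of one 9-axis sensor stream.

    ``stream`` is ``(n, 9)`` in the canonical channel order.  The gyro Y
    channel is drift-corrected (static windows taken from the stream's
    own stationary lead-in) and fused with the accelerometer tilt.
    ``correct_drift=False`` integrates the raw rate — useful to
    demonstrate how fast an uncorrected biased gyro diverges.
    """
    cfg = cfg or FusionConfig()
    drift_cfg = drift_cfg or DriftConfig()
    stream = np.asarray(stream, dtype=float)
    if stream.ndim != 2 or stream.shape[1] != len(CHANNELS):
        raise InvalidParameterError("stream must have shape (n, 9)")
    beta = accel_tilt(stream[:, 0], stream[:, 2])
    gyro_y = stream[:, 4]
    omega = correct_gyro(gyro_y, None, drift_cfg) if correct_drift else gyro_y
    sigma = _complementary_series(omega, beta, cfg)
    return OrientationState(sigma=sigma, tilt=beta, omega_gf=omega)


# ---------------------------------------------------------------------------
# joint angle

@dataclass
class JointAngleSeries:
    """Per-sample wrist angle (hand minus forearm orientation) with ROM summary."""

    t: np.ndarray
    angle: np.ndarray
    max_angle: float = field(init=False)
    range: float = field(init=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if len(self.t) != len(self.angle):
            raise InvalidParameterError("t and angle must have equal length")
        self.max_angle = float(self.angle.max()) if len(self.angle) else float("nan")
        self.range = (float(self.angle.max() - self.angle.min())
                      if len(self.angle) else float("nan"))

    def __len__(self) -> int:
        return len(self.angle)


def joint_angle(hand: OrientationState, forearm: OrientationState,
                t: np.ndarray) -> JointAngleSeries:
    """Wrist joint angle as the difference between the two filtered orientations."""
    if len(hand) != len(forearm) or len(hand) != len(t):
        raise InvalidParameterError(
            f"length mismatch: hand {len(hand)}, forearm {len(forearm)}, t {len(t)}"
        )
    return JointAngleSeries(t=t, angle=hand.sigma - forearm.sigma)


def joint_angle_from_trial(
    trial: RawTrial,
    cfg: FusionConfig | None = None,
    drift_cfg: DriftConfig | None = None,
) -> JointAngleSeries:
    """Run the full fusion pipeline on one (already trimmed) trial."""
    cfg = cfg or FusionConfig(dt=1.0 / trial.fs)
    hand = track_orientation(trial.hand, cfg, drift_cfg)
    forearm = track_orientation(trial.forearm, cfg, drift_cfg)
    return joint_angle(hand, forearm, trial.t)


# ---------------------------------------------------------------------------
# validation experiment

def peak_angle_error_experiment(
    speeds,
    peak_angles,
    mode: str = "one-static",
    n_trials: int = 20,
    noise: SensorNoiseModel | None = None,
    seed: int = 0,
    fs: float = 100.0,
    trim_seconds: float = 1.0,
    lead_in: float = 6.0,
    cfg: FusionConfig | None = None,
    drift_cfg: DriftConfig | None = None,
) -> float:
    """Mean signed peak-angle error over simulated rig trials, degrees.

    Emulates a validation rig driving the joint to predetermined peak
    angles: trial ``i`` targets ``peak_angles[i % len]`` at joint speed
    ``speeds[i % len]``.  In ``one-static`` mode the forearm sensor
    stays level; in ``both-moving`` mode each sensor carries half the
    joint rotation.  Every trial runs the full pipeline (startup trim,
    drift correction, complementary fusion, inter-sensor difference) and
    contributes ``detected peak - true peak`` to the mean.
    """
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    if mode not in ("one-static", "both-moving"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    noise = noise if noise is not None else SensorNoiseModel()
    frac = 0.0 if mode == "one-static" else 0.5
    speeds = list(np.atleast_1d(speeds))
    peaks = list(np.atleast_1d(peak_angles))

    rng = np.random.default_rng(seed)
    dc = drift_cfg or DriftConfig()
    errors = []
    for i in range(n_trials):
        peak = float(peaks[i % len(peaks)])
        speed = float(speeds[i % len(speeds)])
        duration = lead_in + 2 * (1.2 * peak / speed) + 3.0
        # keep enough post-trim samples for the drift-estimation windows
        duration = max(duration, trim_seconds + (dc.min_samples + 2) / fs)
        profile = generate_stop_sign_profile(
            duration=duration, peak_angle=peak, speed=speed, fs=fs, lead_in=lead_in
        )
        trial = synthesize_recording(
            profile, noise=noise, seed=int(rng.integers(0, 2**31 - 1)),
            forearm_fraction=frac,
        )
        trial = trim_startup(trial, trim_seconds)
        series = joint_angle_from_trial(
            trial, cfg or FusionConfig(dt=1.0 / fs), drift_cfg
        )
        errors.append(series.max_angle - peak)
    return float(np.mean(errors))
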