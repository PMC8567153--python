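"""Synthetic wrist-motion trials for a two-sensor wearable IMU setup.

The simulator produces the ``stop sign`` task used to elicit peak active
wrist extension: the joint angle rises smoothly from rest to a peak,
holds, and returns to rest.  Two 9-axis sensors are emulated — one on the
back of the hand, one on the forearm just above the wrist — sharing a
frame so that the joint angle is a single rotation about the common Y
axis.  Accelerometers see gravity projected through the sensor
orientation, gyroscopes see the angular rate plus static bias, slow
linear drift and white noise, and magnetometers see a fixed ambient
field rotated into the sensor frame.

Two movement classes can be generated with a configurable contrast:
reduced peak angle, slower angular velocity and a tremor component for
the impaired (cerebral-palsy-like) class versus typical movement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

#: canonical 9-axis channel order used everywhere in the package
CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz")

#: standard gravity used to convert between g and m/s^2 where needed
STANDARD_GRAVITY = 9.80665

#: fraction of the nominal ramp time spent in each cosine velocity blend
_BLEND_FRACTION = 0.2


@dataclass
class MotionProfile:
    """Ground-truth joint trajectory on a uniform time grid.

    Attributes
    ----------
    t : ndarray
        Time stamps in seconds, strictly increasing, uniform spacing.
    theta_true : ndarray
        Joint angle in degrees; zero at rest.
    omega_true : ndarray
        Angular velocity in degrees/second (analytic derivative of
        ``theta_true``).
    task_name : str
        Free-form task identifier.
    """

    t: np.ndarray
    theta_true: np.ndarray
    omega_true: np.ndarray
    task_name: str = "stop_sign"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.theta_true = np.asarray(self.theta_true, dtype=float)
        self.omega_true = np.asarray(self.omega_true, dtype=float)
        if self.t.ndim != 1 or len(self.t) != len(self.theta_true):
            raise InvalidParameterError("t and theta_true must be 1-D and equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise InvalidParameterError("time grid must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def fs(self) -> float:
        """Sampling rate implied by the (uniform) time grid, Hz."""
        return 1.0 / float(self.t[1] - self.t[0])


@dataclass
class SensorNoiseModel:
    """Imperfections applied to the ideal sensor readings.

    Units: accelerometer noise in g, gyroscope bias/noise in deg/s, drift
    rate in deg/s per second, magnetic field and its noise in microtesla.
    The gyro static bias is per-axis; the drift rate is a common slope
    added to every gyro axis.
    """

    accel_noise_sd: float = 0.01
    gyro_noise_sd: float = 0.2
    gyro_static_bias: tuple[float, float, float] = (0.6, -0.4, 0.5)
    gyro_drift_rate: float = 0.005
    mag_field: tuple[float, float, float] = (22.0, 5.0, -42.0)
    mag_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        for name in ("accel_noise_sd", "gyro_noise_sd", "mag_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    @classmethod
    def noiseless(cls) -> "SensorNoiseModel":
        """An ideal sensor: no noise, no bias, no drift."""
        return cls(
            accel_noise_sd=0.0,
            gyro_noise_sd=0.0,
            gyro_static_bias=(0.0, 0.0, 0.0),
            gyro_drift_rate=0.0,
            mag_noise_sd=0.0,
        )


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-class cohort.

    ``n_cp`` trials receive label 1 (impaired movement: smaller peak
    angle, slower rate, tremor); ``n_typical`` receive label 0.  Peak
    angles are in degrees, speeds are peak angular velocities in deg/s,
    tremor amplitude in degrees and frequency in Hz.
    """

    n_cp: int = 100
    n_typical: int = 100
    cp_peak_angle: float = 40.0
    typical_peak_angle: float = 70.0
    cp_speed: float = 20.0
    typical_speed: float = 40.0
    tremor_amplitude: float = 2.0
    tremor_frequency: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cp < 0 or self.n_typical < 0:
            raise InvalidParameterError("trial counts must be >= 0")
        for name in ("cp_peak_angle", "typical_peak_angle"):
            v = getattr(self, name)
            if not 0 < v <= 120:
                raise InvalidParameterError(f"{name} must lie in (0, 120] degrees")


def _scurve(tau: np.ndarray, speed: float, t_blend: float, t_cruise: float):
    """Angle/rate of a cosine-blended trapezoidal ramp, evaluated at ``tau``.

    The angular velocity rises from 0 to ``speed`` over ``t_blend`` with a
    half-cosine, cruises for ``t_cruise``, and decays symmetrically, so the
    peak rate equals ``speed`` exactly and the total angle swept is
    ``speed * (t_blend + t_cruise)``.
    """
    theta = np.zeros_like(tau)
    omega = np.zeros_like(tau)
    d_blend = speed * t_blend / 2.0

    m1 = (tau >= 0) & (tau < t_blend)
    u = tau[m1]
    omega[m1] = speed * (1 - np.cos(np.pi * u / t_blend)) / 2
    theta[m1] = speed / 2 * (u - t_blend / np.pi * np.sin(np.pi * u / t_blend))

    m2 = (tau >= t_blend) & (tau < t_blend + t_cruise)
    theta[m2] = d_blend + speed * (tau[m2] - t_blend)
    omega[m2] = speed

    m3 = (tau >= t_blend + t_cruise) & (tau <= 2 * t_blend + t_cruise)
    u = tau[m3] - t_blend - t_cruise
    omega[m3] = speed * (1 + np.cos(np.pi * u / t_blend)) / 2
    theta[m3] = (
        d_blend
        + speed * t_cruise
        + speed / 2 * (u + t_blend / np.pi * np.sin(np.pi * u / t_blend))
    )

    m4 = tau > 2 * t_blend + t_cruise
    theta[m4] = speed * (t_blend + t_cruise)
    return theta, omega


def generate_stop_sign_profile(
    duration: float,
    peak_angle: float,
    speed: float,
    tremor_amplitude: float = 0.0,
    tremor_frequency: float = 5.0,
    fs: float = 100.0,
    seed: int | None = None,
    lead_in: float = 0.0,
) -> MotionProfile:
    """Ground-truth joint angle for one stop-sign repetition.

    The angle stays at rest for ``lead_in`` seconds (a static segment the
    drift-estimation step relies on), rises to ``peak_angle`` with peak
    angular velocity ``speed``, holds, and returns to rest; any remaining
    time stays at zero.  An optional tremor sinusoid of the given
    amplitude (degrees) and frequency (Hz) is superposed on the whole
    trajectory.

    Parameters are degrees, deg/s, seconds and Hz.  ``seed`` is accepted
    for interface symmetry; the profile itself is deterministic.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    if fs <= 0:
        raise InvalidParameterError("fs must be > 0")
    if speed <= 0:
        raise InvalidParameterError("speed must be > 0")
    if peak_angle <= 0:
        raise InvalidParameterError("peak_angle must be > 0")
    if tremor_amplitude < 0:
        raise InvalidParameterError("tremor_amplitude must be >= 0")
    if tremor_frequency >= fs / 2:
        raise InvalidParameterError("tremor_frequency must be below the Nyquist rate")

    t_nominal = peak_angle / speed
    t_blend = _BLEND_FRACTION * t_nominal
    t_cruise = t_nominal - t_blend
    t_ramp = t_nominal + t_blend  # one full rise (or fall)

    slack = duration - lead_in - 2 * t_ramp
    if slack < 0:
        raise InvalidParameterError(
            f"duration {duration:g}s too short for ramp-hold-ramp "
            f"(needs >= {lead_in + 2 * t_ramp:g}s at {speed:g} deg/s)"
        )
    hold = slack / 2.0  # remaining half is a trailing rest

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    theta = np.zeros(n)
    omega = np.zeros(n)

    rise0 = lead_in
    fall0 = lead_in + t_ramp + hold
    rising = (t >= rise0) & (t < rise0 + t_ramp)
    holding = (t >= rise0 + t_ramp) & (t < fall0)
    falling = (t >= fall0) & (t < fall0 + t_ramp)

    th, om = _scurve(t[rising] - rise0, speed, t_blend, t_cruise)
    theta[rising], omega[rising] = th, om
    theta[holding] = peak_angle
    th, om = _scurve(t[falling] - fall0, speed, t_blend, t_cruise)
    theta[falling] = peak_angle - th
    omega[falling] = -om

    if tremor_amplitude > 0:
        theta = theta + tremor_amplitude * np.sin(2 * np.pi * tremor_frequency * t)
        omega = omega + (
            tremor_amplitude * 2 * np.pi * tremor_frequency
            * np.cos(2 * np.pi * tremor_frequency * t)
        )

    return MotionProfile(t=t, theta_true=theta, omega_true=omega)


def _rotate_about_y(theta_deg: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """World-frame vector seen in a sensor frame tilted by theta about Y.

    The sign convention makes a level sensor read gravity as (0, 0, 1) g
    and a sensor tilted by +theta read (sin theta, 0, cos theta), so that
    atan2(a_x, a_z) recovers +theta.
    """
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    c, s = np.cos(th), np.sin(th)
    x = c * vec[0] + s * vec[2]
    y = np.full_like(th, float(vec[1]))
    z = -s * vec[0] + c * vec[2]
    return np.stack([x, y, z], axis=-1)


def _sensor_stream(
    theta: np.ndarray,
    omega: np.ndarray,
    t: np.ndarray,
    noise: SensorNoiseModel,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(theta)
    accel = _rotate_about_y(theta, np.array([0.0, 0.0, 1.0]))
    mag = _rotate_about_y(theta, np.asarray(noise.mag_field, dtype=float))

    gyro = np.zeros((n, 3))
    gyro[:, 1] = omega
    gyro += np.asarray(noise.gyro_static_bias, dtype=float)
    gyro += noise.gyro_drift_rate * t[:, None]

    if noise.accel_noise_sd > 0:
        accel = accel + rng.normal(0.0, noise.accel_noise_sd, size=(n, 3))
    if noise.gyro_noise_sd > 0:
        gyro = gyro + rng.normal(0.0, noise.gyro_noise_sd, size=(n, 3))
    if noise.mag_noise_sd > 0:
        mag = mag + rng.normal(0.0, noise.mag_noise_sd, size=(n, 3))

    return np.concatenate([accel, gyro, mag], axis=1)


def synthesize_recording(
    profile: MotionProfile,
    noise: SensorNoiseModel | None = None,
    fs: float | None = None,
    seed: int | None = None,
    label: int | None = None,
    forearm_fraction: float = 0.0,
    meta: dict | None = None,
):
    """Render a ground-truth profile into a two-sensor 9-axis recording.

    By default the forearm sensor stays level and the hand sensor carries
    the whole joint rotation.  ``forearm_fraction`` splits the joint
    angle between the two sensors (hand rotates by ``(1-f)*theta``,
    forearm by ``-f*theta``) so that both-sensors-moving validation
    trials keep the same relative angle; ``f=0.5`` shares the motion
    equally.
    """
    from .io import RawTrial  # local import to avoid a cycle

    if len(profile) == 0:
        raise InvalidParameterError("profile must be non-empty")
    noise = noise if noise is not None else SensorNoiseModel()
    if not 0.0 <= forearm_fraction <= 1.0:
        raise InvalidParameterError("forearm_fraction must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    f = forearm_fraction
    hand = _sensor_stream(
        (1 - f) * profile.theta_true, (1 - f) * profile.omega_true, profile.t, noise, rng
    )
    forearm = _sensor_stream(
        -f * profile.theta_true, -f * profile.omega_true, profile.t, noise, rng
    )
    return RawTrial(
        fs=fs if fs is not None else profile.fs,
        hand=hand,
        forearm=forearm,
        label=label,
        meta=dict(meta or {}, task=profile.task_name),
    )


#: trial layout used for cohort generation: total length, and static
#: lead-in preceding the movement (seconds).  The lead-in leaves ~5 s of
#: stationary data after the 1 s startup trim, enough for the default
#: five 100-sample drift-estimation windows at 100 Hz.
COHORT_DURATION = 15.0
COHORT_LEAD_IN = 6.0


def generate_cohort(
    spec: CohortSpec,
    noise: SensorNoiseModel | None = None,
    fs: float = 100.0,
    duration: float = COHORT_DURATION,
    lead_in: float = COHORT_LEAD_IN,
) -> list:
    """Simulate a labeled cohort of stop-sign trials.

    Returns ``spec.n_cp`` trials labeled 1 and ``spec.n_typical`` labeled
    0, in seeded-shuffled order.  Per-trial kinematics are jittered
    around the class means (15% relative sd on peak angle and speed,
    25% on tremor amplitude, 10% on tremor frequency) so the classes are
    distributions rather than two points.  Identical spec (including
    seed) reproduces the cohort bit for bit.
    """
    if spec.n_cp + spec.n_typical == 0:
        raise InvalidParameterError("cohort must contain at least one trial")
    noise = noise if noise is not None else SensorNoiseModel()
    if spec.tremor_frequency >= fs / 2:
        raise InvalidParameterError("tremor_frequency must be below the Nyquist rate")

    rng = np.random.default_rng(spec.seed)
    trials = []
    plan = [1] * spec.n_cp + [0] * spec.n_typical
    for i, lab in enumerate(plan):
        if lab == 1:
            peak, speed = spec.cp_peak_angle, spec.cp_speed
            trem_a, trem_f = spec.tremor_amplitude, spec.tremor_frequency
        else:
            peak, speed = spec.typical_peak_angle, spec.typical_speed
            trem_a, trem_f = 0.0, spec.tremor_frequency
        peak = float(np.clip(peak * (1 + 0.15 * rng.standard_normal()), 5.0, 120.0))
        speed = float(np.clip(speed * (1 + 0.15 * rng.standard_normal()), 5.0, 200.0))
        if trem_a > 0:
            trem_a = float(max(0.0, trem_a * (1 + 0.25 * rng.standard_normal())))
            trem_f = float(np.clip(trem_f * (1 + 0.10 * rng.standard_normal()), 0.5, fs / 2 - 1))
        # slow movements may not fit the nominal window; stretch if needed
        t_ramp = 1.2 * peak / speed
        dur = max(duration, lead_in + 2 * t_ramp + 1.0)
        profile = generate_stop_sign_profile(
            duration=dur,
            peak_angle=peak,
            speed=speed,
            tremor_amplitude=trem_a,
            tremor_frequency=trem_f,
            fs=fs,
            lead_in=lead_in,
        )
        trial_seed = int(rng.integers(0, 2**31 - 1))
        trials.append(
            synthesize_recording(
                profile,
                noise=noise,
                seed=trial_seed,
                label=lab,
                meta={"trial_id": f"trial{i:04d}", "peak_angle_true": f"{peak:.3f}"},
            )
        )
    order = rng.permutation(len(trials))
    return [trials[j] for j in order]
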