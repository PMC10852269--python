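"""Synthetic maximal-sprint foot trajectories and their IMU corruption chain.

The generator emulates the standard validation protocol for foot-worn inertial
stride estimation: an athlete stands still for ~15 s (for gyro-bias
calibration), then sprints ~70 m in 17 strides whose lengths ramp over the
3.45–4.73 m range at stride speeds ramping 6–9.5 m/s, with ~150 ms ground
contacts.  Every stance is an exact zero-velocity interval, so the whole
pipeline can be validated by parameter recovery without any camera data.

Kinematic form (the literature constrains stance and stride, not the swing
shape): forward motion is a minimum-jerk interpolant per swing, vertical
motion a squared-half-sine lift (default 0.15 m) ending in a short landing
impact whose deceleration produces the resultant-acceleration peak used for
initial-contact detection, and orientation a sagittal-plane pitch oscillation
whose peak angular rate is the tunable that controls gyroscope saturation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

from ._quat import as_rotation
from .conditioning import ImuRecording
from .sensors import (
    GRAVITY,
    SensorSpec,
    blue_trident_gyro,
    blue_trident_high_g,
    blue_trident_low_g,
)

G_VEC = np.array([0.0, 0.0, -GRAVITY])

# peak of the minimum-jerk normalised velocity 30u²(1-u)², reached at u = 1/2
_MINJERK_PEAK_VEL = 1.875


@dataclass(frozen=True)
class SprintProfile:
    """Kinematic prescription of one maximal 80 m-style sprint trial.

    Stride lengths and stride speeds ramp linearly across strides between
    their start/end values; stride k's duration is length/speed.  The pitch
    amplitude is normally derived from ``peak_pitch_rate_dps`` (the maximum
    sagittal angular rate over the whole run, the quantity that determines
    gyroscope saturation); setting ``foot_pitch_amplitude_deg`` instead fixes
    the amplitude directly.
    """

    n_strides: int = 17
    stride_length_start: float = 3.45
    stride_length_end: float = 4.73
    stride_speed_start: float = 6.0
    stride_speed_end: float = 9.5
    contact_time_s: float = 0.150
    stand_still_s: float = 15.0
    foot_lift_m: float = 0.15
    peak_pitch_rate_dps: float = 1800.0
    foot_pitch_amplitude_deg: float | None = None
    landing_speed_ms: float = 1.5
    impact_duration_s: float = 0.005
    stance_micro_motion_ms: float = 0.0
    tail_s: float = 1.0
    rate_hz: float = 9000.0

    def __post_init__(self) -> None:
        if self.n_strides < 2:
            raise ValueError("need at least 2 strides")
        for L in (self.stride_length_start, self.stride_length_end):
            if not 1.0 <= L <= 6.0:
                raise ValueError("stride lengths must lie in [1, 6] m")
        if not 0.08 <= self.contact_time_s <= 0.3:
            raise ValueError("contact time must lie in [0.08, 0.3] s")
        for v in (self.stride_speed_start, self.stride_speed_end):
            if v <= 0 or v > 13.0:
                raise ValueError("stride speeds must lie in (0, 13] m/s")
        if self.stand_still_s < 0 or self.tail_s < 0 or self.rate_hz <= 0:
            raise ValueError("durations and rates must be non-negative")
        if self.impact_duration_s <= 0 or self.landing_speed_ms <= 0:
            raise ValueError("impact parameters must be positive")
        if np.any(self.swing_durations() - self.impact_duration_s < 0.05):
            raise ValueError("swing phase too short for the requested speeds")
        if self.stance_micro_motion_ms > 0.02:
            raise ValueError("stance micro-motion must stay below 0.02 m/s")

    def stride_lengths(self) -> np.ndarray:
        return np.linspace(self.stride_length_start, self.stride_length_end, self.n_strides)

    def stride_speeds(self) -> np.ndarray:
        return np.linspace(self.stride_speed_start, self.stride_speed_end, self.n_strides)

    def stride_durations(self) -> np.ndarray:
        return self.stride_lengths() / self.stride_speeds()

    def swing_durations(self) -> np.ndarray:
        return self.stride_durations() - self.contact_time_s

    def pitch_amplitude_rad(self) -> float:
        if self.foot_pitch_amplitude_deg is not None:
            return math.radians(self.foot_pitch_amplitude_deg)
        # amplitude such that the fastest (shortest-swing) stride reaches the
        # requested peak rate: peak|dθ/dt| = A · 2π · 1.875 / T_swing
        t_min = float(np.min(self.swing_durations()))
        return math.radians(self.peak_pitch_rate_dps) * t_min / (2.0 * math.pi * _MINJERK_PEAK_VEL)


@dataclass
class TrueMotion:
    """Noise-free foot trajectory sampled at the internal simulation rate.

    World frame: x = running direction, z = up.  Quaternions are scalar-first
    sensor→world.  ``stance_windows`` are [start, end] second intervals within
    which the foot speed is < 1e-3 m/s (exactly zero unless stance
    micro-motion was requested); ``footfall_x`` is the forward coordinate of
    each stance, starting with the standing position 0.
    """

    time: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    quaternion: np.ndarray
    angular_rate: np.ndarray
    stance_windows: list[tuple[float, float]]
    footfall_x: np.ndarray
    rate_hz: float

    def specific_force(self) -> np.ndarray:
        """Ideal accelerometer signal in the sensor frame, f = Rᵀ(a − g)."""
        return as_rotation(self.quaternion).inv().apply(self.acceleration - G_VEC)


@dataclass
class GroundTruth:
    """True per-stride lengths/speeds and cumulative distances at the marks."""

    stride_lengths: np.ndarray
    stride_speeds: np.ndarray
    stride_durations: np.ndarray
    footfall_x: np.ndarray
    cumulative_marks: dict[str, float] = field(default_factory=dict)
    mark_footfalls: dict[float, int] = field(default_factory=dict)

    @classmethod
    def from_footfalls(
        cls,
        footfall_x: np.ndarray,
        stride_durations: np.ndarray,
        marks: tuple[float, float] = (20.0, 70.0),
    ) -> "GroundTruth":
        footfall_x = np.asarray(footfall_x, dtype=float)
        lengths = np.diff(footfall_x)
        durations = np.asarray(stride_durations, dtype=float)
        mark_footfalls = {
            float(m): int(np.argmin(np.abs(footfall_x[1:] - m))) + 1 for m in marks
        }
        m1, m2 = marks
        j1, j2 = mark_footfalls[float(m1)], mark_footfalls[float(m2)]
        cumulative = {
            f"0-{m1:g}": float(footfall_x[j1]),
            f"{m1:g}-{m2:g}": float(footfall_x[j2] - footfall_x[j1]),
            f"0-{m2:g}": float(footfall_x[j2]),
        }
        return cls(
            stride_lengths=lengths,
            stride_speeds=lengths / durations,
            stride_durations=durations,
            footfall_x=footfall_x,
            cumulative_marks=cumulative,
            mark_footfalls=mark_footfalls,
        )


def _minjerk(u: np.ndarray, T: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalised minimum-jerk position, velocity, acceleration on u ∈ [0, 1]."""
    s = 10 * u**3 - 15 * u**4 + 6 * u**5
    sd = (30 * u**2 - 60 * u**3 + 30 * u**4) / T
    sdd = (60 * u - 180 * u**2 + 120 * u**3) / T**2
    return s, sd, sdd


def _quintic_coeffs(T: float, p0, v0, a0, p1, v1, a1) -> np.ndarray:
    """Quintic Hermite coefficients matching position/velocity/acceleration ends."""
    M = np.array(
        [
            [1, 0, 0, 0, 0, 0],
            [0, 1, 0, 0, 0, 0],
            [0, 0, 2, 0, 0, 0],
            [1, T, T**2, T**3, T**4, T**5],
            [0, 1, 2 * T, 3 * T**2, 4 * T**3, 5 * T**4],
            [0, 0, 2, 6 * T, 12 * T**2, 20 * T**3],
        ]
    )
    return np.linalg.solve(M, np.array([p0, v0, a0, p1, v1, a1], dtype=float))


def _quintic_eval(c: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p = c[0] + c[1] * t + c[2] * t**2 + c[3] * t**3 + c[4] * t**4 + c[5] * t**5
    v = c[1] + 2 * c[2] * t + 3 * c[3] * t**2 + 4 * c[4] * t**3 + 5 * c[5] * t**4
    a = 2 * c[2] + 6 * c[3] * t + 12 * c[4] * t**2 + 20 * c[5] * t**3
    return p, v, a


def simulate_sprint(profile: SprintProfile, seed: int | None = None) -> tuple[TrueMotion, GroundTruth]:
    """Generate the true foot trajectory and its exactly-known ground truth.

    The trajectory is twice differentiable everywhere, so the ideal specific
    force is finite and continuous; the ground truth is read directly off the
    constructed footfalls, never re-estimated.  ``seed`` is accepted for
    interface symmetry with :func:`synthesize_imu`; the trajectory itself is
    deterministic.
    """
    del seed  # trajectory construction is deterministic
    lengths = profile.stride_lengths()
    durations = profile.stride_durations()
    swings = profile.swing_durations()
    contact = profile.contact_time_s
    t_imp = profile.impact_duration_s
    amp = profile.pitch_amplitude_rad()
    h = profile.foot_lift_m
    v_land = profile.landing_speed_ms
    delta = 0.5 * v_land * t_imp  # height remaining when the impact phase begins

    footfall_x = np.concatenate([[0.0], np.cumsum(lengths)])
    total_t = profile.stand_still_s + float(np.sum(durations)) + profile.tail_s
    rate = profile.rate_hz
    n = int(math.floor(total_t * rate)) + 1
    time = np.arange(n) / rate

    x = np.zeros(n)
    vx = np.zeros(n)
    ax = np.zeros(n)
    z = np.zeros(n)
    vz = np.zeros(n)
    az = np.zeros(n)
    theta = np.zeros(n)
    theta_d = np.zeros(n)

    def seg(t0: float, t1: float) -> tuple[slice, np.ndarray]:
        i0 = int(math.ceil(t0 * rate - 1e-9))
        i1 = min(n, int(math.ceil(t1 * rate - 1e-9)))
        return slice(i0, i1), time[i0:i1] - t0

    stance_windows: list[tuple[float, float]] = [(0.0, profile.stand_still_s)]
    t_cursor = profile.stand_still_s
    for k in range(profile.n_strides):
        t_sw = swings[k]
        t_a = t_sw - t_imp
        x0, x1 = footfall_x[k], footfall_x[k + 1]

        # forward: minimum jerk over the whole swing
        sl, tau = seg(t_cursor, t_cursor + t_sw)
        s, sd, sdd = _minjerk(tau / t_sw, t_sw)
        x[sl] = x0 + (x1 - x0) * s
        vx[sl] = (x1 - x0) * sd
        ax[sl] = (x1 - x0) * sdd

        # pitch oscillation over the whole swing, min-jerk time-warped so the
        # rate and its derivative vanish at both ends
        theta[sl] = amp * np.sin(2 * math.pi * s)
        theta_d[sl] = amp * 2 * math.pi * np.cos(2 * math.pi * s) * sd

        # vertical: squared-half-sine lift plus a quintic blend that delivers
        # the foot to height delta with downward speed v_land ...
        sl_a, tau_a = seg(t_cursor, t_cursor + t_a)
        w = math.pi / t_a
        z[sl_a] = h * np.sin(w * tau_a) ** 2
        vz[sl_a] = h * w * np.sin(2 * w * tau_a)
        az[sl_a] = 2 * h * w**2 * np.cos(2 * w * tau_a)
        c_blend = _quintic_coeffs(t_a, 0, 0, 0, delta, -v_land, 0)
        p, v, a = _quintic_eval(c_blend, tau_a)
        z[sl_a] += p
        vz[sl_a] += v
        az[sl_a] += a

        # ... and a short, sharp landing-impact deceleration to rest.  Its
        # acceleration peak is the initial-contact signature.
        sl_b, tau_b = seg(t_cursor + t_a, t_cursor + t_sw)
        c_imp = _quintic_coeffs(t_imp, delta, -v_land, 0, 0, 0, 0)
        p, v, a = _quintic_eval(c_imp, tau_b)
        z[sl_b], vz[sl_b], az[sl_b] = p, v, a

        # stance: foot at rest on the ground
        t_land = t_cursor + t_sw
        last = k == profile.n_strides - 1
        stance_end = t_land + contact + (profile.tail_s if last else 0.0)
        sl_c, tau_c = seg(t_land, stance_end + (1.0 / rate if last else 0.0))
        x[sl_c] = x1
        if profile.stance_micro_motion_ms > 0:
            # small within-stance wobble (speed ≤ the requested amplitude) to
            # stress the stillness detector; analytic derivatives keep the
            # position/acceleration pair consistent
            f_mm, t_c = 25.0, stance_end - t_land
            wf, we = 2 * math.pi * f_mm, math.pi / t_c
            a_mm = profile.stance_micro_motion_ms / (wf * 1.15)
            sin_f, cos_f = np.sin(wf * tau_c), np.cos(wf * tau_c)
            env = np.sin(we * tau_c) ** 2
            env_d = we * np.sin(2 * we * tau_c)
            env_dd = 2 * we**2 * np.cos(2 * we * tau_c)
            x[sl_c] = x1 + a_mm * sin_f * env
            vx[sl_c] = a_mm * (wf * cos_f * env + sin_f * env_d)
            ax[sl_c] = a_mm * (
                -wf**2 * sin_f * env + 2 * wf * cos_f * env_d + sin_f * env_dd
            )
        stance_windows.append((t_land, stance_end))
        t_cursor += durations[k]

    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(z)):
        raise ValueError("non-finite trajectory generated")

    position = np.column_stack([x, np.zeros(n), z])
    velocity = np.column_stack([vx, np.zeros(n), vz])
    acceleration = np.column_stack([ax, np.zeros(n), az])
    half = 0.5 * theta
    quaternion = np.column_stack(
        [np.cos(half), np.zeros(n), np.sin(half), np.zeros(n)]
    )
    angular_rate = np.column_stack([np.zeros(n), theta_d, np.zeros(n)])

    motion = TrueMotion(
        time=time,
        position=position,
        velocity=velocity,
        acceleration=acceleration,
        quaternion=quaternion,
        angular_rate=angular_rate,
        stance_windows=stance_windows,
        footfall_x=footfall_x,
        rate_hz=rate,
    )
    truth = GroundTruth.from_footfalls(footfall_x, durations)
    return motion, truth


def profile_with_peak_rate(base: SprintProfile, peak_dps: float) -> SprintProfile:
    """Copy of ``base`` whose sagittal pitch rate peaks at ``peak_dps`` °/s."""
    return replace(base, peak_pitch_rate_dps=peak_dps, foot_pitch_amplitude_deg=None)


def _corrupt_channel(
    ideal: np.ndarray,
    time: np.ndarray,
    rate_internal: float,
    spec: SensorSpec,
    rng: np.random.Generator,
    delay_s: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply the datasheet corruption chain to one tri-axial ideal signal.

    Anti-alias low-pass (4th-order Butterworth, zero-phase) → decimation to
    the channel rate → additive white noise of std noise_density·√bandwidth →
    quantisation to the LSB step → clipping at ±range.  Returns the output
    time base, the corrupted samples, and the log of truly clipped samples.
    """
    if spec.antialias_cutoff_hz < 0.499 * rate_internal:
        sos = butter(4, spec.antialias_cutoff_hz, fs=rate_internal, output="sos")
        filtered = sosfiltfilt(sos, ideal, axis=0)
    else:
        filtered = ideal
    n_out = int(math.floor(time[-1] * spec.sample_rate_hz)) + 1
    t_out = np.arange(n_out) / spec.sample_rate_hz
    spline = CubicSpline(time, filtered, axis=0)
    samples = spline(np.clip(t_out - delay_s, time[0], time[-1]))
    if spec.noise_std > 0:
        samples = samples + rng.normal(0.0, spec.noise_std, samples.shape)
    clipped = (
        np.any(np.abs(samples) > spec.range, axis=1)
        if np.isfinite(spec.range)
        else np.zeros(n_out, dtype=bool)
    )
    samples = spec.clip(spec.quantize(samples))
    return t_out, samples, clipped


def synthesize_imu(
    motion: TrueMotion,
    low_spec: SensorSpec | None = None,
    high_spec: SensorSpec | None = None,
    gyro_spec: SensorSpec | None = None,
    gyro_bias: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: int | None = None,
    phase_offset_samples: int = 0,
) -> ImuRecording:
    """Corrupt a true motion into a dual-range IMU recording.

    ``phase_offset_samples`` delays the high-g accelerometer content by that
    many low-rate (1125 Hz) samples relative to the low-g channel — the
    inter-accelerometer phase shift the conditioning stage must recover by
    cross-correlation.  Identical seeds give bit-identical recordings.
    """
    low_spec = low_spec or blue_trident_low_g()
    high_spec = high_spec or blue_trident_high_g()
    gyro_spec = gyro_spec or blue_trident_gyro()
    max_rate = max(low_spec.sample_rate_hz, high_spec.sample_rate_hz, gyro_spec.sample_rate_hz)
    if motion.rate_hz < 4 * max_rate:
        raise ValueError("motion must be sampled at ≥ 4× the highest sensor rate")
    if np.any(~np.isfinite(motion.position)):
        raise ValueError("NaN in motion")

    f_ideal = motion.specific_force()
    omega_ideal = motion.angular_rate + np.asarray(gyro_bias, dtype=float)

    rng = np.random.default_rng(seed)
    delay = phase_offset_samples / low_spec.sample_rate_hz
    t_lo, a_lo, clip_lo = _corrupt_channel(f_ideal, motion.time, motion.rate_hz, low_spec, rng)
    t_hi, a_hi, clip_hi = _corrupt_channel(
        f_ideal, motion.time, motion.rate_hz, high_spec, rng, delay_s=delay
    )
    t_gy, gyro, clip_gy = _corrupt_channel(
        omega_ideal, motion.time, motion.rate_hz, gyro_spec, rng
    )
    if len(t_gy) != len(t_lo):
        raise ValueError("gyro and low-g accelerometer time bases mismatch")

    return ImuRecording(
        time_lo=t_lo,
        accel_lo=a_lo,
        time_hi=t_hi,
        accel_hi=a_hi,
        gyro=gyro,
        low_spec=low_spec,
        high_spec=high_spec,
        gyro_spec=gyro_spec,
        meta={
            "seed": seed,
            "phase_offset_samples": phase_offset_samples,
            "gyro_bias": np.asarray(gyro_bias, dtype=float),
            "clipped_lo": clip_lo,
            "clipped_hi": clip_hi,
            "clipped_gyro": clip_gy,
        },
    )
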