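"""The four-step zero-velocity-update pipeline core.

1. Orientation: strapdown quaternion integration of the unbiased gyroscope,
   stabilised by an error-state (multiplicative) Kalman filter whose only
   measurements are gravity-direction observations at the zero-velocity
   samples, where the accelerometer reads pure gravity.
2. Gravity compensation: a_world = R(q)·f + g_vec.
3. Velocity: trapezoidal integration within each stride with a
   linearly-in-time drift correction forcing v = 0 exactly at both stride
   endpoints.
4. Position: trapezoidal integration of the corrected velocity, anchored at
   the first zero-velocity sample.

Heading (yaw) is unobservable from gravity alone; for a straight-lane sprint
the stride length is the horizontal displacement norm, which a slowly
drifting heading does not affect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from ._quat import (
    as_rotation,
    quat_from_rotvec,
    quat_multiply,
    quat_normalize,
    rotmat_from_quat,
)
from .conditioning import ConditionedSignals, NotStillError
from .sensors import GRAVITY
from .stationary import StationaryEvents

G_VEC = np.array([0.0, 0.0, -GRAVITY])
_UP = np.array([0.0, 0.0, 1.0])


@dataclass
class OrientationTrack:
    """Sensor→world quaternion series with attitude-error variance diagonals."""

    time: np.ndarray
    quaternion: np.ndarray
    covariance_diag: np.ndarray | None = None


@dataclass
class Trajectory:
    """World-frame velocity and position after zero-velocity drift correction."""

    time: np.ndarray
    velocity: np.ndarray
    position: np.ndarray
    stride_intervals: list[tuple[int, int]]


def initialize_orientation(
    conditioned: ConditionedSignals, standing_window: tuple[float, float] | None = None
) -> np.ndarray:
    """Initial quaternion from the standing-period gravity direction.

    Roll and pitch come from the mean specific force; yaw is zero by
    convention (the run direction defines world +x).
    """
    window = standing_window or conditioned.standing_window
    t0, t1 = window
    if t1 - t0 < 0.5:
        raise NotStillError("standing window too short to initialise orientation")
    sel = (conditioned.time >= t0) & (conditioned.time <= t1)
    f = conditioned.accel[sel].mean(axis=0)
    if np.linalg.norm(f) < 0.5 * GRAVITY:
        raise NotStillError("standing-window specific force inconsistent with gravity")
    roll = math.atan2(f[1], f[2])
    pitch = math.atan2(-f[0], math.hypot(f[1], f[2]))
    q_pitch = np.array([math.cos(pitch / 2), 0.0, math.sin(pitch / 2), 0.0])
    q_roll = np.array([math.cos(roll / 2), math.sin(roll / 2), 0.0, 0.0])
    return quat_normalize(quat_multiply(q_pitch, q_roll))


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])


def estimate_orientation(
    conditioned: ConditionedSignals,
    events: StationaryEvents,
    q0: np.ndarray | None = None,
    process_noise_psd: float | None = None,
    meas_noise_rad: float = 0.02,
    p0_diag: tuple[float, float, float] = (1e-4, 1e-4, 1e-2),
    use_updates: bool = True,
) -> OrientationTrack:
    """Error-state Kalman attitude filter with gravity updates at ZV samples.

    The quaternion is propagated per sample by the first-order exponential map
    of the (trapezoid-averaged) angular rate.  The 3-state attitude-error
    covariance accumulates gyro angle random walk between updates; at each
    zero-velocity sample the normalised specific force is treated as a noisy
    observation of the world up-direction in the sensor frame, which corrects
    roll and pitch (yaw stays unobservable and its variance grows).

    ``process_noise_psd`` is the attitude random-walk PSD in rad²/s; by
    default it is derived from the gyro spec's noise density and quantisation
    step.  ``meas_noise_rad`` is the 1-σ gravity-direction error of one
    update, dominated by residual stance micro-dynamics rather than
    accelerometer noise.
    """
    time = conditioned.time
    omega = conditioned.gyro_unbiased
    n = len(time)
    dt = 1.0 / conditioned.sample_rate
    if q0 is None:
        q0 = initialize_orientation(conditioned)
    if process_noise_psd is None:
        spec = conditioned.gyro_spec
        if spec is not None:
            var = spec.noise_std**2
            if math.isfinite(spec.quantization_step):
                var += spec.quantization_step**2 / 12.0
            process_noise_psd = var * dt
        else:
            process_noise_psd = 1e-8

    update_idx = set()
    if use_updates:
        update_idx.update(int(i) for i in events.zero_velocity_indices)
        if events.anchor_index is not None:
            update_idx.add(int(events.anchor_index))

    quats = np.empty((n, 4))
    cov_diag = np.empty((n, 3))
    q = np.asarray(q0, dtype=float).copy()
    P = np.diag(p0_diag).astype(float)
    R_meas = (meas_noise_rad**2) * np.eye(3)
    q_last_update = q.copy()
    t_last_update = time[0]

    for i in range(n):
        if i > 0:
            w = 0.5 * (omega[i - 1] + omega[i]) * dt
            q = quat_multiply(q, quat_from_rotvec(w))
        quats[i] = q
        cov_diag[i] = np.diag(P) + process_noise_psd * (time[i] - t_last_update)
        if i in update_idx:
            # propagate covariance to now: rotate the body-frame error by the
            # relative rotation since the last update, add accumulated random walk
            rel = rotmat_from_quat(q_last_update).T @ rotmat_from_quat(q)
            P = rel.T @ P @ rel + process_noise_psd * (time[i] - t_last_update) * np.eye(3)
            f = conditioned.accel[i]
            norm_f = np.linalg.norm(f)
            if norm_f > 1e-6:
                z = f / norm_f
                Rm = rotmat_from_quat(q)
                h = Rm.T @ _UP
                H = _skew(h)
                S = H @ P @ H.T + R_meas
                K = P @ H.T @ np.linalg.inv(S)
                delta = K @ (z - h)
                q = quat_normalize(quat_multiply(q, quat_from_rotvec(delta)))
                quats[i] = q
                IKH = np.eye(3) - K @ H
                P = IKH @ P @ IKH.T + K @ R_meas @ K.T
            if not np.all(np.isfinite(P)):
                raise FloatingPointError("attitude covariance diverged")
            q_last_update = q.copy()
            t_last_update = time[i]
            cov_diag[i] = np.diag(P)
        # renormalise occasionally against drift of the unit norm
        if i % 1024 == 0:
            q = quat_normalize(q)

    return OrientationTrack(time=time, quaternion=quats, covariance_diag=cov_diag)


def world_linear_acceleration(
    conditioned: ConditionedSignals, orientation: OrientationTrack
) -> np.ndarray:
    """Gravity-compensated acceleration in the world frame, R(q)·f + g_vec."""
    if len(orientation.quaternion) != len(conditioned.accel):
        raise ValueError("orientation and signal lengths differ")
    rot = as_rotation(orientation.quaternion)
    return rot.apply(conditioned.accel) + G_VEC


def integrate_velocity_zupt(
    a_world: np.ndarray,
    time: np.ndarray,
    stride_intervals: list[tuple[int, int]],
) -> np.ndarray:
    """Per-stride trapezoidal velocity with exact linear drift correction.

    Within each stride [i, j] the velocity starts at zero, and the residual
    v(j) is removed by subtracting a correction growing linearly in time, so
    v(i) = v(j) = (0,0,0) exactly.  Samples outside the covered region are
    zero and carry no meaning.
    """
    v = np.zeros_like(a_world)
    for i, j in stride_intervals:
        if j - i < 3:
            raise ValueError("stride interval shorter than 3 samples")
        t = time[i : j + 1]
        raw = cumulative_trapezoid(a_world[i : j + 1], t, axis=0, initial=0.0)
        ramp = ((t - t[0]) / (t[-1] - t[0]))[:, None]
        v[i : j + 1] = raw - ramp * raw[-1]
    return v


def integrate_position(
    velocity: np.ndarray,
    time: np.ndarray,
    stride_intervals: list[tuple[int, int]],
) -> np.ndarray:
    """Trapezoidal position, anchored at zero at the first zero-velocity sample."""
    p = np.zeros_like(velocity)
    if not stride_intervals:
        return p
    start = stride_intervals[0][0]
    end = stride_intervals[-1][1]
    p[start : end + 1] = cumulative_trapezoid(
        velocity[start : end + 1], time[start : end + 1], axis=0, initial=0.0
    )
    p[end + 1 :] = p[end]
    return p


def run_zupt(
    conditioned: ConditionedSignals,
    events: StationaryEvents,
    **orientation_kwargs,
) -> tuple[OrientationTrack, Trajectory]:
    """Steps 2–4 for a segmented trial: orientation, velocity, position."""
    orientation = estimate_orientation(conditioned, events, **orientation_kwargs)
    a_world = world_linear_acceleration(conditioned, orientation)
    velocity = integrate_velocity_zupt(a_world, conditioned.time, events.stride_intervals)
    position = integrate_position(velocity, conditioned.time, events.stride_intervals)
    trajectory = Trajectory(
        time=conditioned.time,
        velocity=velocity,
        position=position,
        stride_intervals=list(events.stride_intervals),
    )
    return orientation, trajectory
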