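"""Minimal scalar-first quaternion helpers.

Quaternions are stored ``(w, x, y, z)`` and represent sensor→world rotations.
Vectorised conversions elsewhere go through ``scipy.spatial.transform.Rotation``
(which is scalar-last); these scalar routines exist for the per-sample
strapdown loop where object overhead matters.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation


def quat_multiply(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q
    w2, x2, y2, z2 = r
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def quat_normalize(q: np.ndarray) -> np.ndarray:
    return np.asarray(q, dtype=float) / math.sqrt(float(np.dot(q, q)))


def quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    """Exponential map: rotation vector (rad) → unit quaternion."""
    angle = math.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
    if angle < 1e-12:
        # second-order small-angle expansion keeps unit norm to machine precision
        half = 0.5 * angle
        w = 1.0 - half * half / 2.0
        s = 0.5 * (1.0 - half * half / 6.0)
    else:
        half = 0.5 * angle
        w = math.cos(half)
        s = math.sin(half) / angle
    return np.array([w, v[0] * s, v[1] * s, v[2] * s])


def rotmat_from_quat(q: np.ndarray) -> np.ndarray:
    """3x3 sensor→world rotation matrix from a scalar-first quaternion."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quat_angle_between(q1: np.ndarray, q2: np.ndarray) -> float:
    """Geodesic angle (rad) between two unit quaternions."""
    d = abs(float(np.dot(q1, q2)))
    return 2.0 * math.acos(min(1.0, d))


def as_rotation(q_wxyz: np.ndarray) -> Rotation:
    """scipy Rotation from scalar-first quaternion array (..., 4)."""
    q = np.asarray(q_wxyz, dtype=float)
    return Rotation.from_quat(np.roll(q, -1, axis=-1))


def from_rotation(rot: Rotation) -> np.ndarray:
    """Scalar-first quaternion array from a scipy Rotation."""
    return np.roll(rot.as_quat(), 1, axis=-1)
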