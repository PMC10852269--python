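"""Dual-range accelerometer fusion and gyroscope bias removal.

Sprint-grade IMUs pair a fine-resolution low-range accelerometer (±16 g,
1125 Hz) with a coarse high-range one (±200 g, 1600 Hz).  At sprinting
intensities the low-g channel clips during swing and foot strike, so the
high-g channel is down-sampled onto the low-g time base, lag-aligned by
cross-correlation, and substituted wherever the low-g channel saturates.
The gyroscope's fixed bias is estimated from the pre-sprint standing period
and subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .sensors import SensorSpec


class NotStillError(RuntimeError):
    """The nominally standing-still window contains motion."""


@dataclass
class ImuRecording:
    """Raw dual-range IMU trial: low-g accel + gyro at 1125 Hz, high-g at 1600 Hz.

    Accelerations are m/s², angular rates rad/s, times seconds from the start
    of the standing period.
    """

    time_lo: np.ndarray
    accel_lo: np.ndarray
    time_hi: np.ndarray
    accel_hi: np.ndarray
    gyro: np.ndarray
    low_spec: SensorSpec
    high_spec: SensorSpec
    gyro_spec: SensorSpec
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, name in ((self.time_lo, "time_lo"), (self.time_hi, "time_hi")):
            dt = np.diff(t)
            if len(dt) == 0 or np.any(dt <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            if np.max(np.abs(dt - dt.mean())) > 1e-6 * dt.mean():
                raise ValueError(f"{name} must be uniform to < 1 ppm")
        if self.accel_lo.shape != (len(self.time_lo), 3):
            raise ValueError("accel_lo must be (n_lo, 3)")
        if self.gyro.shape != (len(self.time_lo), 3):
            raise ValueError("gyro must be (n_lo, 3)")
        if self.accel_hi.shape != (len(self.time_hi), 3):
            raise ValueError("accel_hi must be (n_hi, 3)")
        for arr, spec, name in (
            (self.accel_lo, self.low_spec, "accel_lo"),
            (self.accel_hi, self.high_spec, "accel_hi"),
            (self.gyro, self.gyro_spec, "gyro"),
        ):
            limit = spec.range + min(spec.quantization_step, spec.range)
            if np.isfinite(limit) and np.max(np.abs(arr)) > limit:
                raise ValueError(f"{name} exceeds its sensor range")

    @property
    def sample_rate_lo(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time_lo)))


@dataclass
class ConditionedSignals:
    """Single clean 1125 Hz stream: fused acceleration + unbiased gyro."""

    time: np.ndarray
    accel: np.ndarray
    gyro_unbiased: np.ndarray
    gyro_bias: np.ndarray
    saturation_mask_accel: np.ndarray
    saturation_mask_gyro: np.ndarray
    lag_samples: int
    standing_window: tuple[float, float]
    low_spec: SensorSpec | None = None
    high_spec: SensorSpec | None = None
    gyro_spec: SensorSpec | None = None

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))


def find_standing_window(
    gyro: np.ndarray,
    time: np.ndarray,
    min_duration_s: float = 5.0,
    still_std: float = 0.05,
    block_s: float = 0.25,
) -> tuple[float, float]:
    """Auto-detect the pre-sprint standing period.

    Scans consecutive blocks of ``block_s`` seconds and returns the first run
    of at least ``min_duration_s`` whose gyro-magnitude standard deviation
    stays below ``still_std`` rad/s, trimmed by 0.1 s at the end.  Falls back
    to [0, 15] s (the nominal protocol) when no such run exists.
    """
    fs = 1.0 / float(np.mean(np.diff(time)))
    mag = np.linalg.norm(gyro, axis=1)
    block = max(2, int(round(block_s * fs)))
    n_blocks = len(mag) // block
    if n_blocks == 0:
        return (0.0, 15.0)
    trimmed = mag[: n_blocks * block].reshape(n_blocks, block)
    centred = trimmed - trimmed.mean(axis=1, keepdims=True)
    still = centred.std(axis=1) < still_std
    need = int(np.ceil(min_duration_s / block_s))
    run_start, count = 0, 0
    for i, ok in enumerate(still):
        if ok:
            if count == 0:
                run_start = i
            count += 1
        else:
            if count >= need:
                break
            count = 0
    if count < need:
        return (0.0, 15.0)
    run_end = run_start + count
    t0 = time[run_start * block]
    t1 = time[min(run_end * block, len(time) - 1)] - 0.1
    return (float(t0), float(t1))


def estimate_gyro_bias(
    recording: ImuRecording,
    standing_window: tuple[float, float],
    still_std: float = 0.05,
) -> np.ndarray:
    """Per-axis mean angular rate over the standing window (the fixed bias).

    Raises
    ------
    NotStillError
        If the window is shorter than 2 s or the gyro-magnitude standard
        deviation exceeds ``still_std`` rad/s — the athlete moved.
    """
    t0, t1 = standing_window
    if t1 - t0 < 2.0:
        raise NotStillError("standing window must be at least 2 s long")
    sel = (recording.time_lo >= t0) & (recording.time_lo <= t1)
    if not np.any(sel):
        raise NotStillError("standing window contains no samples")
    g = recording.gyro[sel]
    mag = np.linalg.norm(g, axis=1)
    if mag.std() > still_std:
        raise NotStillError(
            f"not still: |gyro| std {mag.std():.3g} rad/s exceeds {still_std} rad/s"
        )
    return g.mean(axis=0)


def detect_saturation(
    series: np.ndarray, spec: SensorSpec, fraction: float = 0.98
) -> np.ndarray:
    """Flag samples where any axis magnitude reaches ``fraction·range``.

    The sub-unity default guards against near-rail distortion: a channel is
    treated as saturated slightly before its output actually pins.
    """
    if not 0.9 < fraction <= 1.0:
        raise ValueError("fraction must be in (0.9, 1]")
    if not np.isfinite(spec.range):
        return np.zeros(len(series), dtype=bool)
    return np.any(np.abs(series) >= fraction * spec.range, axis=1)


def resample_highg(
    accel_hi: np.ndarray, time_hi: np.ndarray, target_time: np.ndarray
) -> np.ndarray:
    """Linearly down-sample the 1600 Hz high-g stream onto the 1125 Hz stamps.

    Target stamps may overhang the high-g record by at most one high-rate
    sample period (the two rates end on different grid points); the end value
    is held there.  Anything further is an extrapolation request and rejected.
    """
    tol = float(np.mean(np.diff(time_hi)))
    if target_time[0] < time_hi[0] - tol or target_time[-1] > time_hi[-1] + tol:
        raise ValueError("target_time extends beyond the high-g record (extrapolation)")
    out = np.empty((len(target_time), accel_hi.shape[1]))
    for axis in range(accel_hi.shape[1]):
        out[:, axis] = np.interp(target_time, time_hi, accel_hi[:, axis])
    return out


def align_by_crosscorr(
    accel_lo_mag: np.ndarray,
    accel_hi_mag_resampled: np.ndarray,
    max_lag_samples: int = 56,
) -> int:
    """Integer lag (in 1125 Hz samples) of the high-g stream behind the low-g one.

    Maximises the normalised cross-correlation of the resultant magnitudes over
    lags in ``[-max_lag, +max_lag]``; ties break toward the smaller ``|lag|``.
    A positive return value means the high-g content arrives ``lag`` samples
    late and must be advanced by that amount to align.
    """
    a = np.asarray(accel_lo_mag, dtype=float)
    b = np.asarray(accel_hi_mag_resampled, dtype=float)
    if len(a) != len(b):
        raise ValueError("series must have equal length")
    if len(a) < 10 * max_lag_samples:
        raise ValueError("series too short for the requested maximum lag")
    a = a - a.mean()
    b = b - b.mean()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("flat (zero-variance) input")
    lags = sorted(range(-max_lag_samples, max_lag_samples + 1), key=lambda l: (abs(l), l))
    best_lag, best_val = 0, -np.inf
    for lag in lags:
        if lag >= 0:
            x, y = a[: len(a) - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: len(b) + lag]
        denom = np.linalg.norm(x) * np.linalg.norm(y)
        val = float(np.dot(x, y) / denom) if denom > 0 else -np.inf
        if val > best_val + 1e-15:
            best_val, best_lag = val, lag
    return best_lag


def apply_lag(series: np.ndarray, lag_samples: int) -> np.ndarray:
    """Advance a series by ``lag_samples``, zero-padding the vacated edge."""
    out = np.zeros_like(series)
    if lag_samples == 0:
        out[:] = series
    elif lag_samples > 0:
        out[:-lag_samples or None] = series[lag_samples:]
    else:
        out[-lag_samples:] = series[:lag_samples]
    return out


def fuse_accelerometers(
    accel_lo: np.ndarray,
    accel_hi_aligned: np.ndarray,
    saturation_mask: np.ndarray,
    dilate_samples: int = 2,
) -> np.ndarray:
    """Sample-wise switch: high-g where the low-g channel saturates, else low-g.

    The saturation mask is dilated by ``dilate_samples`` on each side so that
    near-rail distortion adjacent to clipped samples is also replaced.
    """
    if accel_lo.shape != accel_hi_aligned.shape:
        raise ValueError("accelerometer streams must have equal shape")
    mask = np.asarray(saturation_mask, dtype=bool)
    if dilate_samples > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, iterations=dilate_samples)
    fused = np.where(mask[:, None], accel_hi_aligned, accel_lo)
    return fused


def condition(
    recording: ImuRecording,
    standing_window: tuple[float, float] | None = None,
    saturation_fraction: float = 0.98,
    max_lag_samples: int = 56,
    dilate_samples: int = 2,
    still_std: float = 0.05,
) -> ConditionedSignals:
    """Full conditioning pass: bias removal, alignment, saturation fusion."""
    if standing_window is None:
        standing_window = find_standing_window(recording.gyro, recording.time_lo)
    bias = estimate_gyro_bias(recording, standing_window, still_std=still_std)
    sat_lo = detect_saturation(recording.accel_lo, recording.low_spec, saturation_fraction)
    hi_rs = resample_highg(recording.accel_hi, recording.time_hi, recording.time_lo)
    lag = align_by_crosscorr(
        np.linalg.norm(recording.accel_lo, axis=1),
        np.linalg.norm(hi_rs, axis=1),
        max_lag_samples,
    )
    hi_aligned = apply_lag(hi_rs, lag)
    fused = fuse_accelerometers(recording.accel_lo, hi_aligned, sat_lo, dilate_samples)
    sat_gyro = detect_saturation(recording.gyro, recording.gyro_spec, saturation_fraction)
    return ConditionedSignals(
        time=recording.time_lo,
        accel=fused,
        gyro_unbiased=recording.gyro - bias,
        gyro_bias=bias,
        saturation_mask_accel=sat_lo,
        saturation_mask_gyro=sat_gyro,
        lag_samples=lag,
        standing_window=standing_window,
        low_spec=recording.low_spec,
        high_spec=recording.high_spec,
        gyro_spec=recording.gyro_spec,
    )
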