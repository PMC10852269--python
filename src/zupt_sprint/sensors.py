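"""Sensor specifications and unit conversions for dual-range foot-mounted IMUs.

All internal math is in SI units (m/s², rad/s).  Vendor datasheets for
sprint-grade IMUs such as the Blue Trident IMeasureU mix unit systems
(g for accelerometer range, °/s for the gyroscope, mg/√Hz noise densities),
so conversion happens here, at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Standard gravity, m/s².
GRAVITY = 9.80665


def g_to_ms2(x: float) -> float:
    """Convert an acceleration from g-units to m/s²."""
    return x * GRAVITY


def dps_to_rads(x: float) -> float:
    """Convert an angular rate from °/s to rad/s."""
    return math.radians(x)


def rads_to_dps(x: float) -> float:
    return math.degrees(x)


@dataclass(frozen=True)
class SensorSpec:
    """One IMU channel's datasheet characteristics, in SI units.

    Parameters
    ----------
    sample_rate_hz
        Output data rate.
    range
        Full-scale magnitude (m/s² for accelerometers, rad/s for gyroscopes).
        ``inf`` models an ideal, unclipped channel.
    bit_resolution
        ADC word length; ``None`` models an ideal, unquantised channel.
    noise_density
        White-noise amplitude density in signal units per √Hz.  The expected
        per-sample noise standard deviation is ``noise_density·√bandwidth_hz``.
    antialias_cutoff_hz
        Cut-off of the channel's internal low-pass anti-alias filter.  Stored
        as the datasheet gives it — some datasheets quote cut-offs above the
        Nyquist margin, and we do not second-guess them.
    bandwidth_hz
        Noise-equivalent bandwidth.
    """

    sample_rate_hz: float
    range: float
    bit_resolution: int | None
    noise_density: float
    antialias_cutoff_hz: float
    bandwidth_hz: float

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.range <= 0:
            raise ValueError("range must be positive")
        if self.bit_resolution is not None and self.bit_resolution <= 0:
            raise ValueError("bit_resolution must be a positive integer")
        if self.noise_density < 0:
            raise ValueError("noise_density must be non-negative")
        if self.antialias_cutoff_hz <= 0 or self.bandwidth_hz <= 0:
            raise ValueError("filter cutoff and bandwidth must be positive")

    @property
    def quantization_step(self) -> float:
        """LSB size, ``2·range / 2^bits``; ``inf`` when unquantised."""
        if self.bit_resolution is None or not math.isfinite(self.range):
            return math.inf
        return 2.0 * self.range / 2.0 ** self.bit_resolution

    @property
    def noise_std(self) -> float:
        """Expected per-sample white-noise standard deviation."""
        return self.noise_density * math.sqrt(self.bandwidth_hz)

    def quantize(self, x: np.ndarray) -> np.ndarray:
        step = self.quantization_step
        if not math.isfinite(step):
            return np.asarray(x, dtype=float)
        return np.round(np.asarray(x, dtype=float) / step) * step

    def clip(self, x: np.ndarray) -> np.ndarray:
        if not math.isfinite(self.range):
            return np.asarray(x, dtype=float)
        return np.clip(x, -self.range, self.range)


# -- Blue Trident IMeasureU channels (datasheet values, converted to SI) -----

_ACCEL_NOISE_DENSITY = 0.23e-3 * GRAVITY  # 0.23 mg/√Hz


def blue_trident_low_g() -> SensorSpec:
    """±16 g accelerometer: 1125 Hz, 16 bit (step ≈ 0.0048 m/s²)."""
    return SensorSpec(
        sample_rate_hz=1125.0,
        range=g_to_ms2(16.0),
        bit_resolution=16,
        noise_density=_ACCEL_NOISE_DENSITY,
        antialias_cutoff_hz=473.0,
        bandwidth_hz=1125.0,
    )


def blue_trident_high_g() -> SensorSpec:
    """±200 g accelerometer: 1600 Hz, 13 bit (step ≈ 0.48 m/s²)."""
    return SensorSpec(
        sample_rate_hz=1600.0,
        range=g_to_ms2(200.0),
        bit_resolution=13,
        noise_density=_ACCEL_NOISE_DENSITY,
        antialias_cutoff_hz=800.0,
        bandwidth_hz=1600.0,
    )


def blue_trident_gyro() -> SensorSpec:
    """±2000 °/s gyroscope: 1125 Hz, 16 bit (step ≈ 0.061 °/s)."""
    return SensorSpec(
        sample_rate_hz=1125.0,
        range=dps_to_rads(2000.0),
        bit_resolution=16,
        noise_density=dps_to_rads(0.015),  # 0.015 (°/s)/√Hz
        antialias_cutoff_hz=473.0,
        bandwidth_hz=773.5,
    )


def ideal_spec(sample_rate_hz: float, bandwidth_hz: float | None = None) -> SensorSpec:
    """A noiseless, unquantised, unclipped channel at the given rate.

    Useful for parameter-recovery studies that isolate algorithmic error from
    sensor error.  The anti-alias cutoff is placed at 45% of the sample rate.
    """
    return SensorSpec(
        sample_rate_hz=sample_rate_hz,
        range=math.inf,
        bit_resolution=None,
        noise_density=0.0,
        antialias_cutoff_hz=0.45 * sample_rate_hz,
        bandwidth_hz=bandwidth_hz if bandwidth_hz is not None else sample_rate_hz,
    )
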