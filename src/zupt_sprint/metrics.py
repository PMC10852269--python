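"""Stride-length and cumulative-distance error measures.

Errors are relative percentages, err = (calc/truth − 1)·100.  Cumulative
distances are evaluated at the course marks (default ~20 m and ~70 m) using
the footfall nearest each mark, the same convention a camera-based reference
uses; speeds divide known distances by IMU-derived durations (the time
between two consecutive zero-velocity samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GroundTruth
from .zupt import Trajectory


def cumulative_distance_error(d_calc, d_truth):
    """Cumulative distance error in percent, (D_calc/D_truth − 1)·100."""
    d_truth = np.asarray(d_truth, dtype=float)
    if np.any(d_truth <= 0):
        raise ValueError("true distance must be positive")
    out = (np.asarray(d_calc, dtype=float) / d_truth - 1.0) * 100.0
    return float(out) if out.ndim == 0 else out


def stride_length_error(s_calc, s_truth):
    """Stride length error in percent, (S_calc/S_truth − 1)·100."""
    return cumulative_distance_error(s_calc, s_truth)


def derive_speeds(lengths, durations):
    """Elementwise speed = length / IMU duration (m/s)."""
    durations = np.asarray(durations, dtype=float)
    if np.any(durations <= 0):
        raise ValueError("durations must be positive")
    out = np.asarray(lengths, dtype=float) / durations
    return float(out) if out.ndim == 0 else out


def stride_table(trajectory: Trajectory, time: np.ndarray | None = None) -> pd.DataFrame:
    """Per-stride summary: horizontal length, duration and speed.

    Stride length is the x–y plane norm of the displacement between
    consecutive zero-velocity samples (the camera reference measures the
    horizontal distance between vertical projections, and vertical drift
    cancels at ground level anyway).
    """
    t = trajectory.time if time is None else time
    rows = []
    for k, (i, j) in enumerate(trajectory.stride_intervals, start=1):
        disp = trajectory.position[j] - trajectory.position[i]
        length = float(np.hypot(disp[0], disp[1]))
        duration = float(t[j] - t[i])
        rows.append(
            {
                "stride": k,
                "start_time_s": float(t[i]),
                "end_time_s": float(t[j]),
                "length_m": length,
                "duration_s": duration,
                "speed_ms": length / duration,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SegmentResult:
    label: str
    d_calc: float
    d_truth: float
    d_err_pct: float
    duration_s: float
    speed_ms: float


@dataclass
class ErrorReport:
    """Per-trial agreement between calculated and true stride quantities."""

    stride_errors_pct: np.ndarray
    stride_lengths_calc: np.ndarray
    stride_lengths_truth: np.ndarray
    stride_speeds: np.ndarray
    segments: dict[str, SegmentResult]
    focal_stride: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": seg.label,
                "D_calc_m": seg.d_calc,
                "D_truth_m": seg.d_truth,
                "D_err_pct": seg.d_err_pct,
                "duration_s": seg.duration_s,
                "speed_ms": seg.speed_ms,
            }
            for seg in self.segments.values()
        ]
        return pd.DataFrame(rows)


def build_error_report(
    strides: pd.DataFrame,
    truth: GroundTruth,
    marks: tuple[float, float] = (20.0, 70.0),
) -> ErrorReport:
    """Compare a calculated stride table against ground truth.

    Requires the detected stride count to match the true one (stride k maps
    to true stride k).  The focal single stride is the one whose start
    footfall lies nearest the far mark, mirroring a camera placed there.
    """
    s_calc = strides["length_m"].to_numpy()
    s_truth = np.asarray(truth.stride_lengths, dtype=float)
    if len(s_calc) != len(s_truth):
        raise ValueError(
            f"detected {len(s_calc)} strides but ground truth has {len(s_truth)}"
        )
    s_err = stride_length_error(s_calc, s_truth)
    durations = strides["duration_s"].to_numpy()
    speeds = derive_speeds(s_calc, durations)

    m1, m2 = marks
    j1 = truth.mark_footfalls.get(float(m1))
    j2 = truth.mark_footfalls.get(float(m2))
    if j1 is None or j2 is None:
        raise ValueError("ground truth lacks the requested course marks")

    cum_calc = np.concatenate([[0.0], np.cumsum(s_calc)])
    t_nodes = np.concatenate(
        [[strides["start_time_s"].iloc[0]], strides["end_time_s"].to_numpy()]
    )
    segments: dict[str, SegmentResult] = {}
    for label, a, b in (
        (f"0-{m1:g}", 0, j1),
        (f"{m1:g}-{m2:g}", j1, j2),
        (f"0-{m2:g}", 0, j2),
    ):
        d_calc = float(cum_calc[b] - cum_calc[a])
        d_truth = float(truth.footfall_x[b] - truth.footfall_x[a])
        duration = float(t_nodes[b] - t_nodes[a])
        segments[label] = SegmentResult(
            label=label,
            d_calc=d_calc,
            d_truth=d_truth,
            d_err_pct=cumulative_distance_error(d_calc, d_truth),
            duration_s=duration,
            speed_ms=d_truth / duration,
        )

    # single validated stride: start footfall nearest the far mark
    k = int(np.argmin(np.abs(truth.footfall_x[:-1] - m2)))
    focal = {
        "stride": k + 1,
        "S_calc": float(s_calc[k]),
        "S_truth": float(s_truth[k]),
        "S_err_pct": float(s_err[k]),
        "speed_ms": float(speeds[k]),
    }
    return ErrorReport(
        stride_errors_pct=s_err,
        stride_lengths_calc=s_calc,
        stride_lengths_truth=s_truth,
        stride_speeds=speeds,
        segments=segments,
        focal_stride=focal,
    )
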