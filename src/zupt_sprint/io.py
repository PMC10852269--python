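"""Plain-text I/O: delimited time-series files, tables, and YAML configs.

Recordings are split across two CSV files because the two accelerometers run
at different rates: the low-rate file carries time_s, ax_lo..az_lo (m/s²) and
gx..gz (rad/s) at 1125 Hz; the high-rate file carries time_s, ax_hi..az_hi at
1600 Hz.  A YAML metadata sidecar records the sensor specifications and the
simulation seed so a recording is self-describing.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .conditioning import ConditionedSignals, ImuRecording
from .metrics import ErrorReport
from .sensors import (
    SensorSpec,
    blue_trident_gyro,
    blue_trident_high_g,
    blue_trident_low_g,
)
from .simulate import GroundTruth, SprintProfile
from .stationary import StationaryEvents

_LO_COLS = ["time_s", "ax_lo", "ay_lo", "az_lo", "gx", "gy", "gz"]
_HI_COLS = ["time_s", "ax_hi", "ay_hi", "az_hi"]


def _spec_to_dict(spec: SensorSpec) -> dict:
    d = dataclasses.asdict(spec)
    if not np.isfinite(d["range"]):
        d["range"] = ".inf"
    return d


def _spec_from_dict(d: dict) -> SensorSpec:
    d = dict(d)
    if d.get("range") in (".inf", "inf"):
        d["range"] = float("inf")
    return SensorSpec(**d)


def write_recording(
    recording: ImuRecording,
    lo_path: str | Path,
    hi_path: str | Path,
    meta_path: str | Path | None = None,
) -> None:
    lo = pd.DataFrame(
        np.column_stack([recording.time_lo, recording.accel_lo, recording.gyro]),
        columns=_LO_COLS,
    )
    hi = pd.DataFrame(
        np.column_stack([recording.time_hi, recording.accel_hi]), columns=_HI_COLS
    )
    lo.to_csv(lo_path, index=False, float_format="%.12g")
    hi.to_csv(hi_path, index=False, float_format="%.12g")
    if meta_path is not None:
        meta = {
            "seed": recording.meta.get("seed"),
            "phase_offset_samples": recording.meta.get("phase_offset_samples", 0),
            "specs": {
                "low_g": _spec_to_dict(recording.low_spec),
                "high_g": _spec_to_dict(recording.high_spec),
                "gyro": _spec_to_dict(recording.gyro_spec),
            },
        }
        Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_recording(
    lo_path: str | Path,
    hi_path: str | Path,
    meta_path: str | Path | None = None,
) -> ImuRecording:
    lo = pd.read_csv(lo_path)
    hi = pd.read_csv(hi_path)
    meta: dict = {}
    if meta_path is not None and Path(meta_path).exists():
        raw = yaml.safe_load(Path(meta_path).read_text())
        specs = raw.get("specs", {})
        low = _spec_from_dict(specs["low_g"]) if "low_g" in specs else blue_trident_low_g()
        high = _spec_from_dict(specs["high_g"]) if "high_g" in specs else blue_trident_high_g()
        gyro = _spec_from_dict(specs["gyro"]) if "gyro" in specs else blue_trident_gyro()
        meta = {k: raw.get(k) for k in ("seed", "phase_offset_samples")}
    else:
        low, high, gyro = blue_trident_low_g(), blue_trident_high_g(), blue_trident_gyro()
    return ImuRecording(
        time_lo=lo["time_s"].to_numpy(),
        accel_lo=lo[["ax_lo", "ay_lo", "az_lo"]].to_numpy(),
        time_hi=hi["time_s"].to_numpy(),
        accel_hi=hi[["ax_hi", "ay_hi", "az_hi"]].to_numpy(),
        gyro=lo[["gx", "gy", "gz"]].to_numpy(),
        low_spec=low,
        high_spec=high,
        gyro_spec=gyro,
        meta=meta,
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "stride": np.arange(1, len(truth.stride_lengths) + 1),
            "S_truth_m": truth.stride_lengths,
            "cumulative_x_m": truth.footfall_x[1:],
            "duration_s": truth.stride_durations,
            "speed_ms": truth.stride_speeds,
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_ground_truth(path: str | Path, marks: tuple[float, float] = (20.0, 70.0)) -> GroundTruth:
    df = pd.read_csv(path)
    footfalls = np.concatenate([[0.0], df["cumulative_x_m"].to_numpy()])
    return GroundTruth.from_footfalls(footfalls, df["duration_s"].to_numpy(), marks)


def write_conditioned(cond: ConditionedSignals, path: str | Path, meta_path: str | Path | None = None) -> None:
    df = pd.DataFrame(
        np.column_stack([cond.time, cond.accel, cond.gyro_unbiased]),
        columns=["time_s", "ax", "ay", "az", "gx", "gy", "gz"],
    )
    df["sat_accel"] = cond.saturation_mask_accel.astype(int)
    df["sat_gyro"] = cond.saturation_mask_gyro.astype(int)
    df.to_csv(path, index=False, float_format="%.9g")
    if meta_path is not None:
        meta = {
            "gyro_bias_rads": [float(b) for b in cond.gyro_bias],
            "lag_samples": int(cond.lag_samples),
            "standing_window_s": [float(t) for t in cond.standing_window],
            "pct_saturated_accel": float(100.0 * cond.saturation_mask_accel.mean()),
            "pct_saturated_gyro": float(100.0 * cond.saturation_mask_gyro.mean()),
        }
        Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def write_events(events: StationaryEvents, time: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "contact_index": events.initial_contacts,
            "contact_time_s": time[events.initial_contacts],
            "zero_velocity_index": events.zero_velocity_indices,
            "zero_velocity_time_s": time[events.zero_velocity_indices],
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def write_trajectory(trajectory, path: str | Path) -> None:
    df = pd.DataFrame(
        np.column_stack([trajectory.time, trajectory.velocity, trajectory.position]),
        columns=["time_s", "vx", "vy", "vz", "x", "y", "z"],
    )
    df.to_csv(path, index=False, float_format="%.9g")


def write_error_report(report: ErrorReport, path: str | Path, meta_path: str | Path | None = None) -> None:
    report.to_frame().to_csv(path, index=False, float_format="%.9g")
    if meta_path is not None:
        Path(meta_path).write_text(yaml.safe_dump({"focal_stride": report.focal_stride}, sort_keys=False))


def save_config(profile: SprintProfile, path: str | Path, specs: dict[str, SensorSpec] | None = None) -> None:
    cfg: dict = {"profile": dataclasses.asdict(profile)}
    if specs:
        cfg["specs"] = {k: _spec_to_dict(v) for k, v in specs.items()}
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def load_config(path: str | Path) -> tuple[SprintProfile, dict[str, SensorSpec]]:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    profile = SprintProfile(**raw.get("profile", {}))
    specs = {k: _spec_from_dict(v) for k, v in raw.get("specs", {}).items()}
    return profile, specs
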