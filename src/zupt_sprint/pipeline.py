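"""End-to-end convenience: raw recording → conditioned → events → strides."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .conditioning import ConditionedSignals, ImuRecording, condition
from .metrics import stride_table
from .stationary import StationaryEvents, detect_stationary_events
from .zupt import OrientationTrack, Trajectory, run_zupt


@dataclass
class PipelineResult:
    conditioned: ConditionedSignals
    events: StationaryEvents
    orientation: OrientationTrack
    trajectory: Trajectory
    strides: pd.DataFrame


def analyze_recording(
    recording: ImuRecording,
    standing_window: tuple[float, float] | None = None,
    condition_kwargs: dict | None = None,
    detection_kwargs: dict | None = None,
    orientation_kwargs: dict | None = None,
) -> PipelineResult:
    """Run the whole zero-velocity-update pipeline on one sprint trial."""
    conditioned = condition(
        recording, standing_window=standing_window, **(condition_kwargs or {})
    )
    events = detect_stationary_events(conditioned, **(detection_kwargs or {}))
    orientation, trajectory = run_zupt(conditioned, events, **(orientation_kwargs or {}))
    return PipelineResult(
        conditioned=conditioned,
        events=events,
        orientation=orientation,
        trajectory=trajectory,
        strides=stride_table(trajectory),
    )
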