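"""Stride segmentation: initial contacts and one zero-velocity sample per contact.

Initial contacts are the dominant peaks of the resultant (fused) acceleration
— the landing impacts.  Within the first 25% of each inter-contact interval,
the 8 stillest samples are selected by a Skog-style rank statistic combining
gyroscope magnitude and gravity-deviated acceleration magnitude (8 samples ≈
5% of a 150 ms contact at 1125 Hz).  The zero-velocity sample is the minimum
angular-rate sample inside the longest consecutive run of selected samples.
The pre-sprint standing period contributes the starting zero-velocity anchor,
so stride 1 is measured from the start line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import rankdata

from .conditioning import ConditionedSignals
from .sensors import GRAVITY


class NoRunningError(RuntimeError):
    """No initial-contact peaks above the running threshold were found."""


@dataclass
class StationaryEvents:
    """Initial contacts, per-contact candidate masks, and zero-velocity samples."""

    initial_contacts: np.ndarray
    candidate_masks: list[np.ndarray]
    zero_velocity_indices: np.ndarray
    stride_intervals: list[tuple[int, int]] = field(default_factory=list)
    anchor_index: int | None = None

    @property
    def n_strides(self) -> int:
        return len(self.stride_intervals)


def detect_initial_contacts(
    accel_resultant: np.ndarray,
    sample_rate_hz: float,
    min_separation_s: float = 0.3,
    min_height: float = 3.0 * GRAVITY,
    search_start: int = 0,
    rel_height: float = 0.4,
) -> np.ndarray:
    """Landing-impact peaks of the resultant acceleration.

    Local maxima above ``min_height`` are accepted greedily in descending
    height with a minimum separation of ``min_separation_s`` (so the tallest
    peak in any conflict — the impact, not a mid-swing extremum — survives).
    Peaks below ``rel_height`` of the tallest one are rejected: the first
    swing out of the standing start has no preceding contact inside the
    separation window, so its (much lower) swing-acceleration maximum must be
    screened out by height.  Samples before ``search_start`` (the standing
    period) are excluded.
    """
    x = np.asarray(accel_resultant, dtype=float)
    region = x[search_start:]
    if len(region) < 2 * int(min_separation_s * sample_rate_hz):
        raise ValueError("signal shorter than twice the minimum peak separation")
    distance = max(1, int(round(min_separation_s * sample_rate_hz)))
    height = max(min_height, rel_height * float(region.max()))
    peaks, _ = find_peaks(region, height=height, distance=distance)
    if len(peaks) == 0:
        raise NoRunningError("no running detected: no resultant-acceleration peaks above 3 g")
    return peaks + search_start


def select_candidates(
    gyro_mag: np.ndarray,
    accel_mag: np.ndarray,
    ic_pair: tuple[int, int],
    k_samples: int = 8,
) -> np.ndarray:
    """Mark the ``k_samples`` stillest samples in the first 25% after a contact.

    Stillness is the rank-sum of the gyroscope magnitude rank and the
    gravity-deviation rank |‖a‖ − g| — a threshold-free reading of the
    adjusted-threshold detectors of the Skog family: lowering a common
    threshold until exactly k samples qualify is the same as keeping the k
    best-ranked samples.  Returns a full-length boolean mask.
    """
    ic_k, ic_next = ic_pair
    start = ic_k + 1
    stop = ic_k + max(1, int(np.floor(0.25 * (ic_next - ic_k))))
    if stop - start < k_samples:
        raise ValueError("candidate window too short for the requested sample count")
    window = slice(start, stop)
    score = rankdata(gyro_mag[window]) + rankdata(np.abs(accel_mag[window] - GRAVITY))
    order = np.argsort(score, kind="stable")[:k_samples]
    mask = np.zeros(len(gyro_mag), dtype=bool)
    mask[start + order] = True
    return mask


def pick_zero_velocity(candidate_mask: np.ndarray, gyro_mag: np.ndarray) -> int:
    """Minimum-angular-rate sample of the longest consecutive candidate run.

    Ties break toward the earliest run and the earliest sample.
    """
    idx = np.flatnonzero(candidate_mask)
    if len(idx) == 0:
        raise ValueError("no candidate samples marked")
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    run = max(runs, key=len)  # max() keeps the earliest of equally long runs
    return int(run[np.argmin(gyro_mag[run])])


def detect_stationary_events(
    conditioned: ConditionedSignals,
    min_separation_s: float = 0.3,
    k_samples: int = 8,
    min_height: float = 3.0 * GRAVITY,
) -> StationaryEvents:
    """Full segmentation of a conditioned trial into stride intervals."""
    fs = conditioned.sample_rate
    time = conditioned.time
    accel_res = np.linalg.norm(conditioned.accel, axis=1)
    gyro_mag = np.linalg.norm(conditioned.gyro_unbiased, axis=1)

    stand_end = conditioned.standing_window[1]
    search_start = int(np.searchsorted(time, stand_end))
    ics = detect_initial_contacts(
        accel_res, fs, min_separation_s, min_height, search_start=search_start
    )

    # the contact after the last one has no successor; size its window with
    # the median preceding inter-contact interval
    if len(ics) > 1:
        median_gap = int(np.median(np.diff(ics)))
    else:
        median_gap = int(0.5 * fs)
    bounds = np.append(ics, min(ics[-1] + median_gap, len(time) - 1))

    masks: list[np.ndarray] = []
    zv: list[int] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        mask = select_candidates(gyro_mag, accel_res, (int(a), int(b)), k_samples)
        masks.append(mask)
        zv.append(pick_zero_velocity(mask, gyro_mag))
    zv_arr = np.asarray(zv, dtype=int)

    # start-line anchor: a zero-velocity sample at the end of the standing
    # period, so integration (and stride 1) starts from the start line
    anchor_t = max(stand_end - 0.1, conditioned.standing_window[0])
    anchor = int(np.searchsorted(time, anchor_t))
    nodes = np.concatenate([[anchor], zv_arr])
    intervals = [(int(i), int(j)) for i, j in zip(nodes[:-1], nodes[1:])]
    return StationaryEvents(
        initial_contacts=ics,
        candidate_masks=masks,
        zero_velocity_indices=zv_arr,
        stride_intervals=intervals,
        anchor_index=anchor,
    )
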