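"""Shared fixtures: simulated sprints at the study's default conditions.

Heavy simulations are session-scoped; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from zupt_sprint import (
    SprintProfile,
    analyze_recording,
    ideal_spec,
    simulate_sprint,
    synthesize_imu,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_profile() -> SprintProfile:
    return SprintProfile()


@pytest.fixture(scope="session")
def sprint_truth(default_profile):
    """True motion + ground truth of the canonical 17-stride ~70 m sprint."""
    return simulate_sprint(default_profile, seed=0)


@pytest.fixture(scope="session")
def ideal_specs():
    return dict(
        low_spec=ideal_spec(1125.0),
        high_spec=ideal_spec(1600.0),
        gyro_spec=ideal_spec(1125.0),
    )


@pytest.fixture(scope="session")
def noiseless_run(sprint_truth, ideal_specs):
    """Full pipeline on the canonical sprint with ideal (noise-free) sensors."""
    motion, truth = sprint_truth
    recording = synthesize_imu(motion, seed=0, **ideal_specs)
    return motion, truth, recording, analyze_recording(recording)


@pytest.fixture(scope="session")
def papergrade_run(sprint_truth):
    """Full pipeline on the canonical sprint with datasheet-grade sensors."""
    motion, truth = sprint_truth
    recording = synthesize_imu(motion, seed=0)
    return motion, truth, recording, analyze_recording(recording)


@pytest.fixture(scope="session")
def short_motion():
    """A lighter 6-stride sprint for tests that sweep many corruptions."""
    profile = SprintProfile(n_strides=6, stand_still_s=6.0, tail_s=0.5)
    return simulate_sprint(profile, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_stationary_motion(duration_s: float = 8.0, rate: float = 9000.0):
    """A foot at rest: the simplest motion for sensor-statics checks."""
    from zupt_sprint.simulate import TrueMotion

    n = int(duration_s * rate) + 1
    time = np.arange(n) / rate
    zeros = np.zeros((n, 3))
    quat = np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
    return TrueMotion(
        time=time,
        position=zeros,
        velocity=zeros.copy(),
        acceleration=zeros.copy(),
        quaternion=quat,
        angular_rate=zeros.copy(),
        stance_windows=[(0.0, duration_s)],
        footfall_x=np.array([0.0]),
        rate_hz=rate,
    )


@pytest.fixture()
def stationary_motion_factory():
    return make_stationary_motion
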