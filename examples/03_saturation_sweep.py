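"""Gyroscope saturation versus stride-length error.

Sweeps the simulated peak foot angular velocity through the gyroscope's
±2000 °/s range.  Once swing rotation rates exceed the range, clipped
samples lose rotation, the attitude estimate mis-projects the large swing
accelerations, and the linear drift correction charges the resulting
spurious end-of-stride velocity as drift — so stride lengths are
systematically underestimated, more severely as the clipped fraction grows.
"""

import numpy as np

from zupt_sprint import SprintProfile, analyze_recording, simulate_sprint, synthesize_imu
from zupt_sprint.simulate import profile_with_peak_rate

print(f"{'peak rate':>10} {'clipped':>9} {'mean stride error':>18}")
for peak_dps in (1500, 1800, 2100, 2400, 2700, 3000):
    profile = profile_with_peak_rate(SprintProfile(), peak_dps)
    motion, truth = simulate_sprint(profile, seed=0)
    recording = synthesize_imu(motion, seed=0)
    result = analyze_recording(recording)
    err = np.mean(result.strides["length_m"].to_numpy() / truth.stride_lengths - 1) * 100
    clipped = 100 * recording.meta["clipped_gyro"].mean()
    print(f"{peak_dps:>7} °/s {clipped:>8.2f}% {err:>17.2f}%")
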