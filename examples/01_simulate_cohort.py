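"""Simulate the six-subject driving cohort and inspect its structure.

Generates six one-hour sessions (128 Hz EEG + 3-axis gyro) with per-minute
drowsiness labels, then prints the cohort's label bookkeeping.
"""

import numpy as np

from drowsekit import SimProfile, simulate_cohort
from drowsekit.io import ALERT, DROWSY, EXCLUDED

sessions = simulate_cohort(SimProfile(), seed=1)

labels = np.concatenate([s.minute_labels for s in sessions])
print(f"{len(sessions)} sessions, {labels.size} one-minute windows total")
print(f"  alert:           {np.sum(labels == ALERT)}")
print(f"  slightly drowsy: {np.sum(labels == DROWSY)}")
print(f"  mid/late stage:  {np.sum(labels == EXCLUDED)}  (excluded from binary analysis)")

s = sessions[0]
print(
    f"\n{s.subject_id}: {s.duration_s:.0f} s, EEG sd {s.eeg.std():.1f} uV "
    f"(peak {np.abs(s.eeg).max():.0f} uV), gyro sd {s.gyro.std():.0f} device units"
)
# the trajectory is monotone: vigilance only degrades over the hour
print("minute labels:", "".join({ALERT: "a", DROWSY: "d", EXCLUDED: "x"}[c] for c in s.minute_labels))
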