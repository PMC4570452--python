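"""Condition one session and extract its per-window features.

Band-pass filters the EEG (4-30 Hz, causal), cuts 2-s epochs, computes
relative band power (theta/alpha/beta, %) and movement power (MP), and
averages 30 epochs per 1-minute window.  Prints per-state medians: alpha
share and MP rise with drowsiness onset, theta share falls.
"""

from drowsekit import SimProfile, simulate_session
from drowsekit.features import session_features
from drowsekit.filters import preprocess
from drowsekit.io import ALERT, DROWSY

session = simulate_session(SimProfile(), subject_index=0, seed=1)
windows = session_features(session, preprocess(session.eeg))

print(f"{session.subject_id}: {len(windows)} windows")
for state, name in [(ALERT, "alert"), (DROWSY, "slightly drowsy")]:
    med = windows[windows["label"] == state][
        ["rbp_theta", "rbp_alpha", "rbp_beta", "mp"]
    ].median()
    print(
        f"  {name:16s} RBP theta/alpha/beta = "
        f"{med.rbp_theta:.1f}/{med.rbp_alpha:.1f}/{med.rbp_beta:.1f} %,  MP = {med.mp:.1f}"
    )
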