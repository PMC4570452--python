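"""Screen each feature's alert-vs-drowsy separability with ROC area.

A folded ROC area of 0.5 means the two classes overlap completely; 1.0
means perfect separation.  Movement power, which captures the head
movements accompanying early drowsiness (yawning, restlessness), separates
the states far better than any single EEG band-power share.
"""

from drowsekit import SimProfile, simulate_cohort
from drowsekit.pipeline import extract_cohort_features
from drowsekit.roc import roc_report

windows = extract_cohort_features(simulate_cohort(SimProfile(), seed=1))
report = roc_report(windows, ["rbp_theta", "rbp_alpha", "rbp_beta", "mp"])
print(report.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(
    "\n'reversed' marks features that discriminate downward "
    "(e.g. theta share is lower in drowsy windows)."
)
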