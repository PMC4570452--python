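"""Recover confusion-matrix counts from reported sensitivity/specificity.

Published evaluations often print only Sens/Spec/Acc percentages.  Given
the class sizes (here 198 drowsy, 68 alert windows), the integer counts
can be reconstructed exactly and the accuracy re-derived — a consistency
check for reported results.
"""

from drowsekit.classify import metrics, reconstruct_confusion

P, N = 198, 68  # drowsy / alert window counts
for sens, spec, label in [
    (96.46, 95.59, "hybrid features, linear kernel"),
    (95.45, 45.59, "EEG features alone, RBF kernel"),
    (93.43, 91.18, "movement power alone, RBF kernel"),
]:
    cm = reconstruct_confusion(sens, spec, P, N)
    acc, _, _ = metrics(cm)
    print(
        f"{label:34s} Sens={sens:6.2f}% Spec={spec:6.2f}%  ->  "
        f"TP={cm.tp} FN={cm.fn} TN={cm.tn} FP={cm.fp}  Acc={acc:.2f}%"
    )
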