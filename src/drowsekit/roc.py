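"""Single-feature discriminability via ROC area.

ROC_area measures how well one feature alone separates alert (-1) from
slightly drowsy (+1) windows.  The raw area under the curve equals the
normalized Mann-Whitney U statistic (tied cross-class pairs count 1/2).
Because a feature may discriminate in either direction — theta power is
*lower* in drowsy windows, for instance — the headline value is folded to
max(A, 1 - A) in [0.5, 1], with the raw area and orientation always
reported alongside: 0.5 means the class distributions overlap completely,
1 means they are perfectly separable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .io import ALERT, DROWSY


@dataclass
class ROCResult:
    feature: str
    raw_auc: float
    auc: float  # folded to [0.5, 1]
    orientation: str  # "as-is" (drowsy scores higher) or "reversed"
    fpr: np.ndarray  # 1 - specificity per threshold
    tpr: np.ndarray  # sensitivity per threshold


def roc_area(scores: np.ndarray, labels: np.ndarray, feature: str = "") -> ROCResult:
    """ROC area of one feature over labeled windows; both classes required.

    raw_auc is computed from midranks (exactly the Mann-Whitney pairwise
    count with ties at 1/2) with +1 as the positive class; auc folds it
    into [0.5, 1] and records whether the discrimination direction was
    reversed.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels == DROWSY
    neg = labels == ALERT
    n1, n0 = int(pos.sum()), int(neg.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_area needs both classes present")
    if pos.sum() + neg.sum() != labels.shape[0]:
        raise ValueError("labels must be -1/+1 only (drop excluded windows first)")
    ranks = rankdata(scores)  # midranks handle ties
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    raw = float(u / (n1 * n0))
    folded = max(raw, 1.0 - raw)
    orientation = "as-is" if raw >= 0.5 else "reversed"
    fpr, tpr, _ = roc_curve(labels, scores if raw >= 0.5 else -scores, pos_label=DROWSY)
    return ROCResult(
        feature=feature, raw_auc=raw, auc=folded, orientation=orientation, fpr=fpr, tpr=tpr
    )


def roc_report(windows: pd.DataFrame, feature_cols: list[str]) -> pd.DataFrame:
    """Fold-reported ROC area per feature over the usable (non-excluded) windows."""
    w = windows[windows["label"].isin([ALERT, DROWSY])]
    rows = []
    for col in feature_cols:
        r = roc_area(w[col].to_numpy(), w["label"].to_numpy(), feature=col)
        rows.append(
            {
                "feature": col,
                "raw_auc": r.raw_auc,
                "auc": r.auc,
                "orientation": r.orientation,
            }
        )
    return pd.DataFrame(rows)
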