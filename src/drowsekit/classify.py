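"""SVM classification of alert (-1) vs slightly drowsy (+1) windows.

Soft-margin SVM with a linear kernel K(x, x') = x . x' or an RBF kernel
K(x, x') = exp(-||x - x'||^2 / (2 g^2)).  The RBF radius ``g`` maps onto
the libsvm gamma parameterization as gamma = 1 / (2 g^2); fitting is
delegated to scikit-learn's SVC (libsvm) with a deterministic
configuration, behind this module's surface.

Evaluation follows leave-one-subject-out (LOSO) cross-validation: each
subject's windows are held out once while all remaining subjects train the
model, and the confusion counts are pooled over all held-out windows.
Hyperparameters (C, and g for RBF) are chosen by exhaustive grid search on
the pooled LOSO accuracy.

Features are standardized (zero mean, unit variance, fitted on the
training fold only) before kernel evaluation by default: RBP is in percent
while MP sits around 10^2 device units, scales an RBF distance cannot mix.
The scaler is stored inside the model so prediction takes raw features.

Decision values of exactly zero map to +1 (drowsy) — the fail-safe
direction for a safety application.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .io import ALERT, DROWSY

KERNELS = ("linear", "rbf")
FEATURE_SETS = {
    "eeg": ["rbp_theta", "rbp_alpha", "rbp_beta"],
    "mp": ["mp"],
    "hybrid": ["rbp_theta", "rbp_alpha", "rbp_beta", "mp"],
}

#: libsvm solver settings fixed for reproducibility
_SVC_OPTS = dict(tol=1e-3, shrinking=True, cache_size=200, max_iter=200_000)


class TrainingError(ValueError):
    """Raised when a training set cannot produce a valid binary model."""


def gamma_from_g(g: float) -> float:
    """Map the RBF radius g (kernel exp(-d^2 / 2g^2)) to libsvm's gamma."""
    if g <= 0:
        raise ValueError(f"g must be positive, got {g}")
    return 1.0 / (2.0 * g * g)


def kernel_eval(kind: str, x: np.ndarray, xp: np.ndarray, g: float | None = None) -> float:
    """Evaluate one kernel value; the reference form used by oracle checks."""
    x = np.asarray(x, dtype=float)
    xp = np.asarray(xp, dtype=float)
    if x.shape != xp.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {xp.shape}")
    if kind == "linear":
        return float(np.dot(x, xp))
    if kind == "rbf":
        if g is None or g <= 0:
            raise ValueError("rbf kernel needs g > 0")
        d2 = float(np.sum((x - xp) ** 2))
        return float(np.exp(-d2 / (2.0 * g * g)))
    raise ValueError(f"unknown kernel {kind!r}")


@dataclass
class SVMModel:
    """A trained scaler + SVM, self-contained for prediction.

    ``support_vectors_`` are stored in the standardized space;
    ``scale_mean``/``scale_std`` hold the affine transform fitted on the
    training fold (identity when scaling is disabled).
    """

    kernel: str
    C: float
    g: float | None
    scale_mean: np.ndarray
    scale_std: np.ndarray
    support_vectors_: np.ndarray
    dual_coef_: np.ndarray
    intercept_: float
    feature_names: list[str] = field(default_factory=list)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.scale_mean.shape[0]:
            raise ValueError(
                f"expected {self.scale_mean.shape[0]} features, got {X.shape[1]}"
            )
        return (X - self.scale_mean) / self.scale_std

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """w . phi(x) + b via the stored support-vector expansion."""
        Z = self.transform(X)
        S = self.support_vectors_
        if self.kernel == "linear":
            K = Z @ S.T
        else:
            d2 = ((Z[:, None, :] - S[None, :, :]) ** 2).sum(axis=2)
            K = np.exp(-d2 / (2.0 * self.g * self.g))
        return K @ self.dual_coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class labels; a decision value of exactly 0 maps to +1 (drowsy)."""
        return np.where(self.decision_function(X) >= 0.0, DROWSY, ALERT)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kernel": self.kernel,
            "C": self.C,
            "g": self.g,
            "scale_mean": self.scale_mean.tolist(),
            "scale_std": self.scale_std.tolist(),
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_,
            "feature_names": self.feature_names,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SVMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            kernel=d["kernel"],
            C=d["C"],
            g=d["g"],
            scale_mean=np.asarray(d["scale_mean"], dtype=float),
            scale_std=np.asarray(d["scale_std"], dtype=float),
            support_vectors_=np.asarray(d["support_vectors"], dtype=float),
            dual_coef_=np.asarray(d["dual_coef"], dtype=float),
            intercept_=float(d["intercept"]),
            feature_names=list(d["feature_names"]),
        )


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "rbf",
    C: float = 1.0,
    g: float | None = 1.0,
    scale: bool = True,
    feature_names: list[str] | None = None,
) -> SVMModel:
    """Fit a soft-margin SVM; both classes must be present in the training set."""
    if kernel not in KERNELS:
        raise ValueError(f"kernel must be one of {KERNELS}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    classes = set(np.unique(y))
    if classes != {ALERT, DROWSY}:
        raise TrainingError(f"training labels must contain both -1 and +1, got {sorted(classes)}")
    if scale:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std > 0, std, 1.0)
    else:
        mean = np.zeros(X.shape[1])
        std = np.ones(X.shape[1])
    Z = (X - mean) / std
    if kernel == "rbf":
        svc = SVC(kernel="rbf", C=C, gamma=gamma_from_g(g), **_SVC_OPTS)
    else:
        svc = SVC(kernel="linear", C=C, **_SVC_OPTS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # max_iter cap may warn on pathological folds
        svc.fit(Z, y)
    # libsvm orders classes ascending (-1, +1), so its decision function is
    # already oriented with +1 positive.
    return SVMModel(
        kernel=kernel,
        C=float(C),
        g=None if kernel == "linear" else float(g),
        scale_mean=mean,
        scale_std=std,
        support_vectors_=svc.support_vectors_.copy(),
        dual_coef_=svc.dual_coef_[0].copy(),
        intercept_=float(svc.intercept_[0]),
        feature_names=list(feature_names or []),
    )


def predict(model: SVMModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


@dataclass
class ConfusionMatrix:
    """Binary confusion counts with +1 (drowsy) as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == DROWSY) & (y_pred == DROWSY))),
        tn=int(np.sum((y_true == ALERT) & (y_pred == ALERT))),
        fp=int(np.sum((y_true == ALERT) & (y_pred == DROWSY))),
        fn=int(np.sum((y_true == DROWSY) & (y_pred == ALERT))),
    )


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(Accuracy%, Sensitivity%, Specificity%); undefined components are NaN.

    Acc = (TP+TN)/(TP+TN+FP+FN), Sens = TP/(TP+FN), Spec = TN/(TN+FP),
    each times 100.
    """
    acc = 100.0 * (cm.tp + cm.tn) / cm.total if cm.total else float("nan")
    pos, neg = cm.tp + cm.fn, cm.tn + cm.fp
    if pos == 0 or neg == 0:
        warnings.warn("confusion matrix lacks one class; Sens or Spec undefined")
    sens = 100.0 * cm.tp / pos if pos else float("nan")
    spec = 100.0 * cm.tn / neg if neg else float("nan")
    return acc, sens, spec


def reconstruct_confusion(
    sens_pct: float, spec_pct: float, positives: int, negatives: int
) -> ConfusionMatrix:
    """Invert printed Sensitivity/Specificity (%) plus class counts into counts.

    TP and TN are the nearest integers to sens*P/100 and spec*N/100; warns
    when the re-derived percentages disagree with the inputs by more than
    0.005 (i.e. when no integer pre-image matches at 2-decimal precision).
    """
    if not (0 <= sens_pct <= 100 and 0 <= spec_pct <= 100):
        raise ValueError("sensitivity/specificity must be in [0, 100]")
    if positives <= 0 or negatives <= 0:
        raise ValueError("positive and negative counts must be > 0")
    tp = int(round(sens_pct * positives / 100.0))
    tn = int(round(spec_pct * negatives / 100.0))
    cm = ConfusionMatrix(tp=tp, tn=tn, fp=negatives - tn, fn=positives - tp)
    re_sens = 100.0 * tp / positives
    re_spec = 100.0 * tn / negatives
    if abs(round(re_sens, 2) - sens_pct) > 0.005 or abs(round(re_spec, 2) - spec_pct) > 0.005:
        warnings.warn(
            f"no exact integer pre-image: ({sens_pct}, {spec_pct}) re-derives to "
            f"({re_sens:.2f}, {re_spec:.2f})"
        )
    return cm


@dataclass
class CVResult:
    """Leave-one-subject-out outcome: per-round and pooled performance."""

    kernel: str
    C: float
    g: float | None
    round_accuracies: dict[str, float]
    pooled: ConfusionMatrix
    n_windows: int
    fold_errors: dict[str, str] = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return metrics(self.pooled)[0]

    @property
    def sensitivity(self) -> float:
        return metrics(self.pooled)[1]

    @property
    def specificity(self) -> float:
        return metrics(self.pooled)[2]


def _usable(windows: pd.DataFrame) -> pd.DataFrame:
    w = windows[windows["label"].isin([ALERT, DROWSY])]
    # fixed ordering for a deterministic solver input
    return w.sort_values(["subject", "window_index"]).reset_index(drop=True)


def loso_crossval(
    windows: pd.DataFrame,
    feature_cols: list[str],
    kernel: str = "rbf",
    C: float = 1.0,
    g: float | None = 1.0,
    scale: bool = True,
) -> CVResult:
    """Leave-one-subject-out cross-validation on labeled windows.

    Excluded windows (label 0) are dropped first.  Each subject is held out
    once; confusion counts are pooled over all held-out windows, so the
    pooled accuracy is the count-weighted accuracy over every usable
    window.  A fold whose training data collapses to a single class is
    recorded in ``fold_errors`` and its windows are left out of the pool.
    """
    w = _usable(windows)
    subjects = sorted(w["subject"].unique())
    if len(subjects) < 2:
        raise TrainingError(f"LOSO needs >= 2 subjects, got {len(subjects)}")
    pooled = ConfusionMatrix(0, 0, 0, 0)
    round_acc: dict[str, float] = {}
    fold_errors: dict[str, str] = {}
    for subj in subjects:
        test = w[w["subject"] == subj]
        train = w[w["subject"] != subj]
        try:
            model = train_svm(
                train[feature_cols].to_numpy(),
                train["label"].to_numpy(),
                kernel=kernel,
                C=C,
                g=g,
                scale=scale,
                feature_names=feature_cols,
            )
        except TrainingError as exc:
            fold_errors[subj] = str(exc)
            continue
        pred = model.predict(test[feature_cols].to_numpy())
        cm = confusion(test["label"].to_numpy(), pred)
        pooled = pooled + cm
        round_acc[subj] = 100.0 * (cm.tp + cm.tn) / cm.total
    return CVResult(
        kernel=kernel,
        C=float(C),
        g=None if kernel == "linear" else float(g),
        round_accuracies=round_acc,
        pooled=pooled,
        n_windows=len(w),
        fold_errors=fold_errors,
    )


def default_grid(n: int = 7) -> np.ndarray:
    """Logarithmic grid spanning the 0.01-10 search range with ~n points."""
    return np.round(np.logspace(-2, 1, n), 6)


def full_grid() -> np.ndarray:
    """The exhaustive 0.01:0.01:10 grid (1000 points per axis).

    With the RBF kernel this is 10^6 LOSO evaluations — hours at desk
    scale; prefer :func:`default_grid` unless replicating the full sweep.
    """
    warnings.warn("full 0.01:0.01:10 grid: 10^6 RBF grid points; this is expensive")
    return np.round(np.arange(0.01, 10.0 + 1e-9, 0.01), 2)


def grid_optimize(
    windows: pd.DataFrame,
    feature_cols: list[str],
    kernel: str = "rbf",
    C_grid: np.ndarray | None = None,
    g_grid: np.ndarray | None = None,
    scale: bool = True,
) -> CVResult:
    """Exhaustive (C, g) search maximizing pooled LOSO accuracy.

    Ties are broken toward the smallest C, then the smallest g.  For the
    linear kernel only C is searched and g is ignored.
    """
    C_grid = default_grid() if C_grid is None else np.asarray(C_grid, dtype=float)
    if C_grid.size == 0:
        raise ValueError("empty C grid")
    if kernel == "rbf":
        g_grid = default_grid() if g_grid is None else np.asarray(g_grid, dtype=float)
        if g_grid.size == 0:
            raise ValueError("empty g grid")
        g_values: list[float | None] = sorted(g_grid)
    else:
        g_values = [None]
    best: CVResult | None = None
    for C in sorted(C_grid):
        for g in g_values:
            res = loso_crossval(windows, feature_cols, kernel, C, g, scale)
            if best is None or res.accuracy > best.accuracy:
                best = res
    assert best is not None
    return best
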