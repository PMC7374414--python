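"""Feature fusion, SVM variants, and repeated cross-validated evaluation.

The recording descriptor is the serial concatenation of the 13 MFCC values
and the 20 LTP histogram values (a 1x33 vector).  Four SVM kernels are
evaluated — linear, quadratic, cubic and Gaussian — all one-vs-one for
multiclass, with features z-scored on each training fold.  Kernel scale s
enters MATLAB-style, dividing the inputs: the Gaussian kernel is
exp(-||x-z||^2 / s^2) and the polynomial kernels (1 + x.z / s^2)^degree.
"Automatic" scale resolves to sqrt(n_features), a deterministic stand-in
for subsampled median-distance heuristics.

Evaluation follows the repeated stratified k-fold protocol: per repeat,
folds are reshuffled, out-of-fold predictions pooled into one confusion
matrix, and the metric suite (accuracy, sensitivity, specificity, PPV,
NPV, error, all in percent) averaged across repeats.  For K > 2 classes
the class-conditional metrics are one-vs-rest per class, macro-averaged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .ltp_features import LtpFeatures
from .mfcc_features import MfccFeatures

KERNELS = ("linear", "quadratic", "cubic", "gaussian")
KERNEL_ALIASES = {"l": "linear", "q": "quadratic", "c": "cubic", "g": "gaussian"}

N_MFCC = 13
N_LTP = 20
FUSED_DIM = N_MFCC + N_LTP

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv", "error")


@dataclass
class SvmSpec:
    """Kernel choice and hyperparameters; defaults mirror a plain C=1 one-vs-one SVM."""

    kernel: str = "cubic"
    kernel_scale: float | str = "automatic"  # positive number, or sqrt(n_features)
    box_constraint: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        self.kernel = KERNEL_ALIASES.get(self.kernel, self.kernel)
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}, got {self.kernel!r}")
        if isinstance(self.kernel_scale, str):
            if self.kernel_scale not in ("automatic", "auto"):
                raise ValueError("kernel_scale must be a positive number or 'automatic'")
        elif self.kernel_scale <= 0:
            raise ValueError("kernel_scale must be positive")
        if self.box_constraint <= 0:
            raise ValueError("box_constraint must be positive")

    def resolve_scale(self, n_features: int) -> float:
        if isinstance(self.kernel_scale, str):
            return math.sqrt(n_features)
        return float(self.kernel_scale)


@dataclass
class EvalReport:
    """Repeated-CV outcome: averaged confusion matrix plus the metric suite."""

    classes: list[str]
    confusion: np.ndarray  # mean per-repeat pooled confusion, rows = actual
    metrics: dict[str, float]  # percentages; NaN marks an undefined 0/0 ratio
    n_folds: int
    n_repeats: int
    per_repeat_accuracies: list[float]

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "metrics": {k: (None if np.isnan(v) else v) for k, v in self.metrics.items()},
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
            "per_repeat_accuracies": self.per_repeat_accuracies,
        }


def fuse(mfcc: MfccFeatures | np.ndarray, ltp: LtpFeatures | np.ndarray) -> np.ndarray:
    """Serial concatenation MFCC (13) then LTP (20) -> 1x33 fused vector."""
    m = mfcc.coeffs if isinstance(mfcc, MfccFeatures) else np.asarray(mfcc, dtype=np.float64)
    t = ltp.values if isinstance(ltp, LtpFeatures) else np.asarray(ltp, dtype=np.float64)
    if m.shape != (N_MFCC,):
        raise ValueError(f"expected {N_MFCC} MFCC values, got shape {m.shape}")
    if t.shape != (N_LTP,):
        raise ValueError(f"expected {N_LTP} LTP values, got shape {t.shape}")
    return np.concatenate([m, t])


def build_svm(spec: SvmSpec, n_features: int) -> Pipeline | SVC:
    """Unfitted estimator for ``spec`` (scaler + SVC pipeline when standardizing)."""
    s = spec.resolve_scale(n_features)
    common = dict(C=spec.box_constraint, decision_function_shape="ovo")
    if spec.kernel == "linear":
        svc = SVC(kernel="linear", **common)
    elif spec.kernel in ("quadratic", "cubic"):
        degree = 2 if spec.kernel == "quadratic" else 3
        svc = SVC(kernel="poly", degree=degree, gamma=1.0 / s**2, coef0=1.0, **common)
    else:
        svc = SVC(kernel="rbf", gamma=1.0 / s**2, **common)
    if spec.standardize:
        return Pipeline([("scale", StandardScaler()), ("svm", svc)])
    return svc


def train_svm(features: np.ndarray, labels, spec: SvmSpec):
    """Fit an SVM on the full feature matrix (z-scored internally if configured)."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D (n_samples, n_features) matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes to train a classifier")
    model = build_svm(spec, X.shape[1])
    model.fit(X, y)
    return model


def _safe_pct(num: float, den: float) -> float:
    return float("nan") if den == 0 else 100.0 * num / den


def compute_metrics(confusion: np.ndarray, positive_index: int | None = None) -> dict[str, float]:
    """Metric suite from a confusion matrix (rows actual, columns predicted).

    For a 2x2 matrix ``positive_index`` selects the positive class (default:
    the second row).  For K > 2 the sensitivity/specificity/PPV/NPV are
    computed one-vs-rest per class and macro-averaged; accuracy is overall
    trace/total.  Ratios with zero denominator come back as NaN rather than
    raising.
    """
    c = np.asarray(confusion, dtype=np.float64)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(c < 0):
        raise ValueError("confusion counts must be nonnegative")
    total = c.sum()
    acc = _safe_pct(np.trace(c), total)
    k = c.shape[0]
    if k == 2:
        classes = [positive_index if positive_index is not None else 1]
    else:
        classes = list(range(k))
    sen, spe, ppv, npv = [], [], [], []
    for i in classes:
        tp = c[i, i]
        fn = c[i, :].sum() - tp
        fp = c[:, i].sum() - tp
        tn = total - tp - fn - fp
        sen.append(_safe_pct(tp, tp + fn))
        spe.append(_safe_pct(tn, tn + fp))
        ppv.append(_safe_pct(tp, tp + fp))
        npv.append(_safe_pct(tn, tn + fn))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN macro average
        out = {
            "accuracy": acc,
            "sensitivity": float(np.nanmean(sen)) if not all(np.isnan(sen)) else float("nan"),
            "specificity": float(np.nanmean(spe)) if not all(np.isnan(spe)) else float("nan"),
            "ppv": float(np.nanmean(ppv)) if not all(np.isnan(ppv)) else float("nan"),
            "npv": float(np.nanmean(npv)) if not all(np.isnan(npv)) else float("nan"),
        }
    out["error"] = 100.0 - acc if not np.isnan(acc) else float("nan")
    return out


def cross_validate(
    features: np.ndarray,
    labels,
    spec: SvmSpec,
    k: int = 10,
    repeats: int = 100,
    seed: int = 0,
    positive_label: str | None = None,
) -> EvalReport:
    """Repeated stratified k-fold evaluation.

    Each repeat reshuffles the folds (seeded with ``seed + repeat``), fits
    the model on k-1 folds — standardization statistics come from the
    training folds only — pools the held-out predictions into a confusion
    matrix, and scores it; metrics are means across repeats.  If some class
    has fewer than ``k`` members the fold count is reduced (with a warning)
    so stratification stays exact.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > X.shape[0]:
        raise ValueError("more folds than samples")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    k_eff = int(min(k, counts.min()))
    if k_eff < k:
        warnings.warn(
            f"smallest class has {counts.min()} samples; reducing folds {k} -> {k_eff}"
        )
        k_eff = max(k_eff, 2)
    if positive_label is None and classes.size == 2 and "abnormal" in classes:
        positive_label = "abnormal"
    pos_idx = None
    if classes.size == 2 and positive_label is not None:
        pos_idx = int(np.flatnonzero(classes == positive_label)[0])

    confusions = []
    accuracies = []
    metric_rows = []
    for rep in range(repeats):
        skf = StratifiedKFold(
            n_splits=k_eff, shuffle=True, random_state=(seed + rep) % (2**31)
        )
        pred = np.empty(y.shape, dtype=y.dtype)
        for train_idx, test_idx in skf.split(X, y):
            model = build_svm(spec, X.shape[1])
            model.fit(X[train_idx], y[train_idx])
            pred[test_idx] = model.predict(X[test_idx])
        c = _sk_confusion(y, pred, labels=classes)
        confusions.append(c)
        m = compute_metrics(c, positive_index=pos_idx)
        metric_rows.append(m)
        accuracies.append(m["accuracy"])

    mean_conf = np.mean(confusions, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_metrics = {
            name: float(np.nanmean([row[name] for row in metric_rows]))
            for name in METRIC_NAMES
        }
    return EvalReport(
        classes=[str(c) for c in classes],
        confusion=mean_conf,
        metrics=mean_metrics,
        n_folds=k_eff,
        n_repeats=repeats,
        per_repeat_accuracies=accuracies,
    )
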