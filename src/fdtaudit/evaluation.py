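"""Partitioning protocols and the slice-level metric suite.

Two stratified protocols are provided: an 80/10/10 hold-out split and
5-fold stratified cross-validation (``StratifiedKFold(n_splits=5,
shuffle=True, random_state=42)``), both preserving class proportions to
within one sample per fold.  Metrics follow imbalanced-multiclass
practice: per-class precision/recall/F1, macro-F1 (the primary summary —
equal weight per class), support-weighted F1, macro one-vs-rest ROC AUC,
and a row-normalized confusion matrix (each true class sums to 1).
Bootstrap confidence intervals resample slices i.i.d. (there is no
patient grouping to respect at slice level) and report the 2.5/97.5
percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "FoldAssignment",
    "MetricsReport",
    "stratified_split",
    "classification_report",
    "bootstrap_ci",
]

HOLDOUT_FRACTIONS = (0.8, 0.1, 0.1)  # train / val / test
KFOLD_SEED = 42


@dataclass(frozen=True)
class FoldAssignment:
    """Per-sample fold index. Holdout folds: 0 = train, 1 = val, 2 = test."""

    fold: np.ndarray
    protocol: str  # "holdout" | "kfold"
    seed: int
    n_folds: int

    def indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.fold == fold)[0]


def stratified_split(
    labels: Sequence,
    protocol: str = "holdout",
    seed: int = KFOLD_SEED,
    n_folds: int = 5,
) -> FoldAssignment:
    """Deterministic stratified partition of a label vector."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if protocol == "kfold":
        if counts.min() < n_folds:
            raise ValueError("every class needs at least n_folds samples")
        fold = np.empty(len(labels), dtype=int)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for k, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            fold[test_idx] = k
        return FoldAssignment(fold, "kfold", seed, n_folds)
    if protocol == "holdout":
        if counts.min() < 3:
            raise ValueError("every class needs at least 3 samples for 80/10/10")
        idx = np.arange(len(labels))
        trainval, test = train_test_split(
            idx, test_size=HOLDOUT_FRACTIONS[2], stratify=labels, random_state=seed
        )
        val_frac = HOLDOUT_FRACTIONS[1] / (HOLDOUT_FRACTIONS[0] + HOLDOUT_FRACTIONS[1])
        train, val = train_test_split(
            trainval, test_size=val_frac, stratify=labels[trainval], random_state=seed
        )
        fold = np.zeros(len(labels), dtype=int)
        fold[val] = 1
        fold[test] = 2
        return FoldAssignment(fold, "holdout", seed, 3)
    raise ValueError(f"unknown protocol {protocol!r}")


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    per_class: dict  # class -> {precision, recall, f1, support}
    macro_f1: float
    weighted_f1: float
    macro_auc_ovr: Optional[float]
    confusion: np.ndarray  # row-normalized, rows = true classes
    classes: tuple
    bootstrap: Optional[dict] = None

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "macro_auc_ovr": self.macro_auc_ovr,
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
        }
        if self.bootstrap:
            d["bootstrap"] = self.bootstrap
        return d


def classification_report(y_true, y_pred, scores=None, classes=None) -> MetricsReport:
    """Accuracy, per-class P/R/F1, macro/weighted F1, macro OvR AUC.

    ``scores``: per-class probability matrix aligned with ``classes``
    (needed for AUC; midrank tie handling via trapezoidal ROC).  A class
    absent from ``y_true`` has undefined AUC and is excluded from the
    macro average with a warning.
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if classes is None:
        classes = tuple(np.unique(np.concatenate([y_true, y_pred])))
    classes = tuple(classes)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=list(classes), zero_division=0
    )
    per_class = {
        str(c): {
            "precision": float(p), "recall": float(r), "f1": float(f),
            "support": int(s),
        }
        for c, p, r, f, s in zip(classes, prec, rec, f1, support)
    }
    macro_f1 = float(np.mean(f1))
    weighted_f1 = float(np.average(f1, weights=support)) if support.sum() else 0.0
    cm = confusion_matrix(y_true, y_pred, labels=list(classes)).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    cm_norm = np.divide(cm, row_sums, out=np.zeros_like(cm), where=row_sums > 0)
    macro_auc = None
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        aucs = []
        for j, c in enumerate(classes):
            pos = (y_true == c).astype(int)
            if pos.min() == pos.max():
                warnings.warn(f"class {c!r} absent from y_true: AUC excluded from macro")
                continue
            aucs.append(roc_auc_score(pos, scores[:, j]))
        macro_auc = float(np.mean(aucs)) if aucs else None
    return MetricsReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        per_class=per_class,
        macro_f1=macro_f1,
        weighted_f1=weighted_f1,
        macro_auc_ovr=macro_auc,
        confusion=cm_norm,
        classes=classes,
    )


def bootstrap_ci(
    y_true,
    y_pred,
    metric: Callable = accuracy_score,
    n_resamples: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple:
    """Percentile bootstrap CI of a metric; returns (point, lower, upper)."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    n = len(y_true)
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_resamples)
    for b in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        stats[b] = metric(y_true[idx], y_pred[idx])
    point = float(metric(y_true, y_pred))
    lower, upper = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return point, float(lower), float(upper)
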