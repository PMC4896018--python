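"""Quantitative evaluation: confusion matrices, derived metrics, ROC/AUC,
exact McNemar comparisons and learning-curve diagnostics.

The abnormal label is the positive class throughout.  Degenerate 0/0 ratios
are reported as NaN with an explicit flag, except F1 which is defined as 0
when there are no true positives (so imbalanced folds stay comparable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "RocCurve",
    "McNemarResult",
    "LearningCurve",
    "confusion",
    "metrics",
    "majority_margin",
    "roc_auc",
    "mcnemar_exact",
    "learning_curve",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts over actual x predicted {normal, abnormal}."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion matrix cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


@dataclass(frozen=True)
class MetricsReport:
    """The six derived metrics; undefined 0/0 ratios are NaN and flagged."""

    accuracy: float
    f1: float
    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    undefined: frozenset = frozenset()

    @property
    def accuracy_percent(self) -> int:
        """Accuracy as an integer percent (presentation rounding)."""
        return round(100.0 * self.accuracy)

    def rounded(self) -> dict:
        """Display form: accuracy as integer percent, others to 2 decimals."""
        out = {"accuracy_percent": self.accuracy_percent}
        for name in ("f1", "ppv", "npv", "sensitivity", "specificity"):
            value = getattr(self, name)
            out[name] = None if math.isnan(value) else round(value, 2)
        return out


def confusion(predicted: Sequence[bool], actual: Sequence[bool]) -> ConfusionMatrix:
    """Count the 2x2 confusion cells (abnormal = positive class)."""
    if len(predicted) != len(actual):
        raise ValueError("predicted and actual label lists differ in length")
    if not predicted:
        raise ValueError("cannot build a confusion matrix from no predictions")
    tn = fp = fn = tp = 0
    for p, a in zip(predicted, actual):
        if a:
            tp += bool(p)
            fn += not p
        else:
            fp += bool(p)
            tn += not p
    return ConfusionMatrix(tn=tn, fp=fp, fn=fn, tp=tp)


def _ratio(num: int, den: int, name: str, undefined: set) -> float:
    if den == 0:
        undefined.add(name)
        return float("nan")
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, F1, PPV, NPV, sensitivity and specificity from 2x2 counts."""
    if cm.n == 0:
        raise ValueError("confusion matrix is empty")
    undefined: set[str] = set()
    accuracy = (cm.tp + cm.tn) / cm.n
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity", undefined)
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity", undefined)
    ppv = _ratio(cm.tp, cm.tp + cm.fp, "ppv", undefined)
    npv = _ratio(cm.tn, cm.tn + cm.fn, "npv", undefined)
    if cm.tp == 0:
        f1 = 0.0
    else:
        f1 = 2 * ppv * sensitivity / (ppv + sensitivity)
    return MetricsReport(accuracy=accuracy, f1=f1, ppv=ppv, npv=npv,
                         sensitivity=sensitivity, specificity=specificity,
                         undefined=frozenset(undefined))


def majority_margin(accuracy_percent_rounded: float,
                    majority_class_percent: float) -> float:
    """Accuracy margin over the majority class, in percentage points.

    Takes the accuracy already rounded to an integer percent (the form in
    which accuracies are reported) and the majority-class prevalence percent;
    returns their difference to 2 decimals.
    """
    if not (0 <= accuracy_percent_rounded <= 100
            and 0 <= majority_class_percent <= 100):
        raise ValueError("percent arguments must lie in [0, 100]")
    return round(accuracy_percent_rounded - majority_class_percent, 2)


@dataclass(frozen=True)
class RocCurve:
    """ROC curve points over all score thresholds, with trapezoidal AUC."""

    fpr: tuple
    tpr: tuple
    thresholds: tuple
    auc: float


def roc_auc(scores: Sequence[float], actual: Sequence[bool]) -> RocCurve:
    """ROC curve and area under it for continuous abnormality scores."""
    if len(scores) != len(actual):
        raise ValueError("scores and labels differ in length")
    y = np.asarray(actual, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(y, np.asarray(scores, dtype=float))
    return RocCurve(fpr=tuple(fpr), tpr=tuple(tpr), thresholds=tuple(thresholds),
                    auc=float(_trapezoid_auc(fpr, tpr)))


@dataclass(frozen=True)
class McNemarResult:
    """Discordant-pair counts and the exact binomial two-sided p-value."""

    b: int  # reports only method A got wrong
    c: int  # reports only method B got wrong
    p_value: float
    zero_discordance: bool = False


def mcnemar_exact(pred_a: Sequence[bool], pred_b: Sequence[bool],
                  actual: Sequence[bool]) -> McNemarResult:
    """Exact McNemar test between two classifiers on paired predictions.

    b and c count reports where exactly one method errs; the two-sided
    p-value doubles the smaller binomial(b+c, 1/2) tail, clipped at 1.
    """
    if not (len(pred_a) == len(pred_b) == len(actual)):
        raise ValueError("prediction and label lists differ in length")
    b = c = 0
    for pa, pb, y in zip(pred_a, pred_b, actual):
        correct_a = bool(pa) == bool(y)
        correct_b = bool(pb) == bool(y)
        if not correct_a and correct_b:
            b += 1
        elif correct_a and not correct_b:
            c += 1
    n = b + c
    if n == 0:
        return McNemarResult(b=0, c=0, p_value=1.0, zero_discordance=True)
    p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n, 0.5)))
    return McNemarResult(b=b, c=c, p_value=p)


@dataclass(frozen=True)
class LearningCurve:
    """Train/validation accuracy (mean, SD over folds) vs training-set size."""

    sizes: tuple
    train_mean: tuple
    train_sd: tuple
    val_mean: tuple
    val_sd: tuple

    def __post_init__(self) -> None:
        if list(self.sizes) != sorted(set(self.sizes)):
            raise ValueError("sizes must be strictly increasing")


def learning_curve(candidate, docs: Sequence[Sequence[str]],
                   labels: Sequence[bool], sizes: Sequence[int], seed: int,
                   folds: int = 5) -> LearningCurve:
    """Bias/variance diagnostic: accuracy as a function of training-set size.

    For each requested size, runs the candidate through the usual stratified
    k-fold CV but fits on a stratified subsample of each fold's training
    portion; subsamples are nested (smaller sizes are subsets of larger) so
    the curves vary smoothly in size.
    """
    # local import: modeling depends on this module for metrics types
    from .modeling import _fit_candidate_on, _cv_folds

    sizes = [int(s) for s in sizes]
    if list(sizes) != sorted(set(sizes)):
        raise ValueError("sizes must be strictly increasing")
    n = len(docs)
    cap = math.floor(n * (folds - 1) / folds)
    if sizes and sizes[-1] > cap:
        raise ValueError(
            f"max size {sizes[-1]} exceeds the {folds}-fold fitting capacity {cap}")
    y = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)

    train_acc = np.zeros((len(sizes), folds))
    val_acc = np.zeros((len(sizes), folds))
    for f, (fit_idx, val_idx) in enumerate(_cv_folds(y, folds, seed)):
        # one stratified shuffle per fold; size-s subsample = first s entries,
        # interleaving classes to keep the subsample stratified at every s
        pos = [i for i in fit_idx if y[i]]
        neg = [i for i in fit_idx if not y[i]]
        rng.shuffle(pos)
        rng.shuffle(neg)
        prop = len(pos) / len(fit_idx)
        for s_i, size in enumerate(sizes):
            n_pos = min(len(pos), max(1, round(size * prop)))
            n_neg = min(len(neg), size - n_pos)
            sub = pos[:n_pos] + neg[:n_neg]
            clf = _fit_candidate_on(candidate, [docs[i] for i in sub], y[sub],
                                    seed=seed)
            train_pred = clf.predict_docs([docs[i] for i in sub])
            val_pred = clf.predict_docs([docs[i] for i in val_idx])
            train_acc[s_i, f] = np.mean(train_pred == y[sub])
            val_acc[s_i, f] = np.mean(val_pred == y[val_idx])

    return LearningCurve(
        sizes=tuple(sizes),
        train_mean=tuple(train_acc.mean(axis=1)),
        train_sd=tuple(train_acc.std(axis=1)),
        val_mean=tuple(val_acc.mean(axis=1)),
        val_sd=tuple(val_acc.std(axis=1)),
    )
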