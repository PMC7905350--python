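"""Confusion metrics, ROC/AUC, stratified k-fold cross-validation, reports."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .types import FeatureSet


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    """2x2 cross-tabulation with positive class = 1 (fatigue)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    for v in (y_true, y_pred):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def rates(counts: ConfusionCounts, decimals: Optional[int] = 2):
    """(sensitivity, specificity, accuracy) as percentages.

    Report values are rounded to ``decimals`` places (pass None for raw).
    Zero denominators raise, since the corresponding rate is undefined.
    """
    if counts.tp + counts.fn == 0:
        raise ZeroDivisionError("no positives: sensitivity undefined")
    if counts.tn + counts.fp == 0:
        raise ZeroDivisionError("no negatives: specificity undefined")
    sens = 100.0 * counts.tp / (counts.tp + counts.fn)
    spec = 100.0 * counts.tn / (counts.tn + counts.fp)
    acc = 100.0 * (counts.tp + counts.tn) / counts.total
    if decimals is not None:
        sens, spec, acc = (round(v, decimals) for v in (sens, spec, acc))
    return sens, spec, acc


def roc_auc(y_true, scores):
    """ROC points by threshold sweep and trapezoidal AUC.

    The curve starts at (0, 0), ends at (1, 1) and is monotone in both
    coordinates; tied scores move diagonally in one step, so the trapezoidal
    area equals the Mann-Whitney statistic with ties counted 1/2.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC curve")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y_true[order]
    s_sorted = scores[order]
    # group tied scores into single sweep steps
    boundaries = np.nonzero(np.diff(s_sorted))[0]
    stops = np.append(boundaries, len(s_sorted) - 1)
    tps = np.cumsum(y_sorted == 1)[stops]
    fps = np.cumsum(y_sorted == 0)[stops]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    points = np.column_stack([fpr, tpr])
    return points, auc


def aggregate_accuracies(accuracies, decimals: Optional[int] = 2):
    """Mean and sample (n-1) standard deviation of per-fold/subject accuracies."""
    acc = np.asarray(accuracies, dtype=float)
    mean = float(np.mean(acc))
    sd = float(np.std(acc, ddof=1)) if acc.size > 1 else 0.0
    if decimals is not None:
        mean, sd = round(mean, decimals), round(sd, decimals)
    return mean, sd


def stratified_folds(y, k: int, seed: int = 0):
    """Disjoint, as-balanced-as-possible stratified folds over the index set."""
    y = np.asarray(y)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    return [np.sort(np.asarray(f)) for f in folds]


def kfold_cv(
    features: FeatureSet,
    k: int,
    trainer: Callable[[FeatureSet, FeatureSet, int], np.ndarray],
    seed: int = 0,
):
    """Stratified k-fold cross-validation of a trainer callable.

    ``trainer(train_fs, val_fs, fold_seed)`` must return continuous scores
    for the validation rows; accuracy is taken at the 0.5 threshold
    (strictly greater = positive). Returns a dict with per-fold accuracies
    (percent), their mean and sample SD, and the pooled confusion counts.
    """
    folds = stratified_folds(features.y, k, seed)
    all_idx = np.arange(len(features))
    fold_acc = []
    pooled_true, pooled_pred, pooled_scores = [], [], []
    for fi, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, val_idx)
        train_fs = features.subset(train_idx)
        val_fs = features.subset(val_idx)
        scores = np.asarray(trainer(train_fs, val_fs, seed + fi))
        preds = (scores > 0.5).astype(int)
        acc = 100.0 * float(np.mean(preds == val_fs.y))
        fold_acc.append(acc)
        pooled_true.append(val_fs.y)
        pooled_pred.append(preds)
        pooled_scores.append(scores)
    mean, sd = aggregate_accuracies(fold_acc, decimals=None)
    counts = confusion(np.concatenate(pooled_true), np.concatenate(pooled_pred))
    return {
        "fold_accuracies": fold_acc,
        "mean_accuracy": mean,
        "sd_accuracy": sd,
        "counts": counts,
        "pooled_scores": np.concatenate(pooled_scores),
        "pooled_true": np.concatenate(pooled_true),
        "folds": [f.tolist() for f in folds],
    }


def dense_param_count(layer_sizes) -> int:
    """Weights plus one bias per non-input node of a fully connected net.

    A 320-30-1 architecture has 320*30 + 30 + 30*1 + 1 = 9661 parameters.
    """
    sizes = list(layer_sizes)
    if len(sizes) < 2:
        raise ValueError("need at least input and output layers")
    return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))


def evaluation_report(y_true, scores) -> dict:
    """Full report: counts at the 0.5 rule, rates, ROC points and AUC."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    preds = (scores > 0.5).astype(int)
    counts = confusion(y_true, preds)
    sens, spec, acc = rates(counts, decimals=None)
    points, auc = roc_auc(y_true, scores)
    return {
        "counts": {"TP": counts.tp, "TN": counts.tn, "FP": counts.fp, "FN": counts.fn},
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "sensitivity_display": round(sens, 2),
        "specificity_display": round(spec, 2),
        "accuracy_display": round(acc, 2),
        "roc": points.tolist(),
        "auc": auc,
    }
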