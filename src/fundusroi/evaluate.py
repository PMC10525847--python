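"""Evaluation: AUC, cut-off tuning, per-class and micro-average metrics,
Normal-state handling, repeated-run confidence intervals, significance tests,
ROC export, and the single-label misclassification matrix.

Conventions:

* an image is predicted disease-positive iff its probability is **strictly
  greater** than the class cut-off;
* cut-offs are tuned to maximize sensitivity x specificity over the candidate
  set {0, 1, midpoints of consecutive sorted unique scores}, ties resolved
  toward the lower threshold;
* "Normal" is derived: truly Normal iff all six labels are 0, predicted
  Normal iff no probability exceeds its cut-off.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .types import DISEASES, LabelVector

CLASS_NAMES = DISEASES + ("normal",)


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is empty (e.g. single-class AUC)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        if self.total == 0:
            raise UndefinedMetricError("accuracy undefined on empty counts")
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise UndefinedMetricError("sensitivity undefined without positives")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise UndefinedMetricError("specificity undefined without negatives")
        return self.tn / (self.tn + self.fp)


@dataclass(frozen=True)
class ThresholdSet:
    """Per-disease cut-offs in canonical order."""

    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(DISEASES):
            raise ValueError("need six thresholds")
        for v in self.values:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"threshold {v} outside [0, 1]")

    def __getitem__(self, disease: str) -> float:
        return self.values[DISEASES.index(disease)]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def _validate_binary(labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise UndefinedMetricError("AUC/threshold undefined: one class absent")
    return pos, neg


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank (Mann-Whitney) AUC: P(random positive outranks random negative),
    ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _validate_binary(np.asarray(labels))
    ranks = stats.rankdata(scores)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def confusion_at(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> ConfusionCounts:
    """Confusion counts with the strict score > threshold positivity rule."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores > threshold
    truth = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def threshold_candidates(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(np.asarray(scores, dtype=float))
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.unique(np.concatenate(([0.0], mids, [1.0])))


def tune_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Cut-off maximizing sensitivity x specificity (exhaustive over candidate
    cuts; ties go to the lower threshold, favouring sensitivity)."""
    scores = np.asarray(scores, dtype=float)
    _validate_binary(np.asarray(labels))
    best_t, best_prod = 0.0, -1.0
    for t in threshold_candidates(scores):
        c = confusion_at(scores, labels, float(np.clip(t, 0.0, 1.0)))
        prod = c.sensitivity * c.specificity
        if prod > best_prod:
            best_t, best_prod = float(t), prod
    return best_t


def micro_average(per_class: Sequence[ConfusionCounts]) -> Tuple[float, float, float]:
    """Pooled-count micro accuracy, sensitivity, and specificity."""
    if not per_class:
        raise ValueError("need at least one class")
    tp = sum(c.tp for c in per_class)
    tn = sum(c.tn for c in per_class)
    fp = sum(c.fp for c in per_class)
    fn = sum(c.fn for c in per_class)
    if tp + tn + fp + fn == 0 or tp + fn == 0 or tn + fp == 0:
        raise UndefinedMetricError("micro-average denominator is zero")
    return (
        (tp + tn) / (tp + tn + fp + fn),
        tp / (tp + fn),
        tn / (tn + fp),
    )


def normal_eval(
    predictions: Sequence[Sequence[float]],
    labels: Sequence[LabelVector],
    thresholds: ThresholdSet,
) -> ConfusionCounts:
    """Binary evaluation of the derived Normal state: truly Normal iff the
    label vector is all-zero; predicted Normal iff every probability is at or
    below its cut-off."""
    preds = np.asarray(predictions, dtype=float)
    if preds.shape[0] != len(labels):
        raise ValueError("predictions and labels misaligned")
    t = thresholds.as_array()
    pred_normal = ~(preds > t).any(axis=1)
    true_normal = np.asarray([lv.is_normal for lv in labels])
    return ConfusionCounts(
        tp=int(np.sum(pred_normal & true_normal)),
        tn=int(np.sum(~pred_normal & ~true_normal)),
        fp=int(np.sum(pred_normal & ~true_normal)),
        fn=int(np.sum(~pred_normal & true_normal)),
    )


def run_ci(values: Sequence[float]) -> Tuple[float, float]:
    """Student-t 95% interval over repeated runs: (mean, half-width)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need >= 2 runs for a confidence interval")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    half = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
    return mean, half


def significance(runs_a: Sequence[float], runs_b: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value between two sets of per-run metrics."""
    a = np.asarray(runs_a, dtype=float)
    b = np.asarray(runs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def misclassification_matrix(
    predictions: Sequence[Sequence[float]],
    labels: Sequence[LabelVector],
    thresholds: ThresholdSet,
) -> np.ndarray:
    """7x7 count matrix over single-label (or all-zero) images only.

    Rows are the true class (six diseases then Normal); columns the predicted
    classes. Every disease whose probability exceeds its cut-off increments
    its column; an all-negative prediction increments the Normal column.
    Multi-label images are excluded.
    """
    preds = np.asarray(predictions, dtype=float)
    t = thresholds.as_array()
    n_cls = len(CLASS_NAMES)
    matrix = np.zeros((n_cls, n_cls), dtype=np.int64)
    for probs, lv in zip(preds, labels):
        if lv.n_positive > 1:
            continue
        row = lv.as_tuple().index(1) if lv.n_positive == 1 else n_cls - 1
        positive = probs > t
        if not positive.any():
            matrix[row, n_cls - 1] += 1
        else:
            for col in np.flatnonzero(positive):
                matrix[row, col] += 1
    return matrix


def roc_export(
    scores: Sequence[float], labels: Sequence[int], out_path: Path | str
) -> Path:
    """Write a CSV of (threshold, fpr, tpr) at every candidate cut.

    The trapezoidal area under the exported curve equals :func:`auc` (scores
    are expected to be probabilities strictly inside (0, 1); a score exactly
    at an endpoint can never flip under the strict-inequality rule).
    """
    scores = np.asarray(scores, dtype=float)
    _validate_binary(np.asarray(labels))
    rows = []
    for t in sorted(threshold_candidates(scores), reverse=True):
        c = confusion_at(scores, labels, float(np.clip(t, 0.0, 1.0)))
        fpr = c.fp / (c.fp + c.tn)
        tpr = c.tp / (c.tp + c.fn)
        rows.append((float(t), fpr, tpr))
    out_path = Path(out_path)
    with out_path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["threshold", "fpr", "tpr"])
        for row in rows:
            writer.writerow([repr(v) for v in row])
    return out_path


def roc_area_from_file(path: Path | str) -> float:
    """Trapezoidal area under an exported ROC CSV."""
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    fpr, tpr = data[:, 1], data[:, 2]
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------
# report assembly


def classification_report(
    predictions: np.ndarray,
    labels: Sequence[LabelVector],
    thresholds: ThresholdSet,
) -> Dict:
    """Per-class AUC/accuracy/sensitivity/specificity, the derived Normal row,
    and pooled micro-averages, as a plain nested dict (JSON-ready)."""
    preds = np.asarray(predictions, dtype=float)
    label_mat = np.asarray([lv.as_tuple() for lv in labels], dtype=int)
    per_class: Dict[str, Dict[str, float]] = {}
    counts: List[ConfusionCounts] = []
    for j, name in enumerate(DISEASES):
        c = confusion_at(preds[:, j], label_mat[:, j], thresholds.values[j])
        counts.append(c)
        per_class[name] = {
            "auc": auc(preds[:, j], label_mat[:, j]),
            "accuracy": c.accuracy,
            "sensitivity": c.sensitivity,
            "specificity": c.specificity,
            "threshold": thresholds.values[j],
        }
    def _safe(fn):
        try:
            return fn()
        except UndefinedMetricError:
            return None

    normal = normal_eval(preds, labels, thresholds)
    per_class["normal"] = {
        "accuracy": _safe(lambda: normal.accuracy),
        "sensitivity": _safe(lambda: normal.sensitivity),
        "specificity": _safe(lambda: normal.specificity),
    }
    micro_acc, micro_sens, micro_spec = micro_average(counts)
    return {
        "per_class": per_class,
        "micro": {
            "accuracy": micro_acc,
            "sensitivity": micro_sens,
            "specificity": micro_spec,
        },
        "n_images": int(preds.shape[0]),
        "n_classes": len(DISEASES),
    }


def aggregate_runs(reports: Sequence[Dict]) -> Dict:
    """Combine per-run reports into mean +/- 95% half-width per metric."""
    if len(reports) < 2:
        raise ValueError("need >= 2 runs to aggregate")

    def _collect(path_fn):
        values = [path_fn(r) for r in reports]
        if any(v is None for v in values):
            return None, None
        return run_ci(values)

    out: Dict = {"n_runs": len(reports), "per_class": {}, "micro": {}}
    for name in reports[0]["per_class"]:
        out["per_class"][name] = {}
        for metric in reports[0]["per_class"][name]:
            mean, half = _collect(lambda r: r["per_class"][name][metric])
            out["per_class"][name][metric] = {"mean": mean, "half_width": half}
    for metric in reports[0]["micro"]:
        mean, half = _collect(lambda r: r["micro"][metric])
        out["micro"][metric] = {"mean": mean, "half_width": half}
    return out
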