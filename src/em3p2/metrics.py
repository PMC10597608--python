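"""Evaluation metrics: ROC-AUC, minority precision, selective-prediction curves.

The selective-prediction ("I don't know") analysis retains a prediction when
its uncertainty u is at or below a threshold and reports accuracy among the
retained predictions.  Because the denominator under rejection is a modelling
choice, both readings are reported: accuracy over retained predictions only,
and accuracy with rejections counted as errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .data_io import DataError
from .evidential import EvidentialOutput, avuc_counts

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC of positive-class scores; ties contribute 1/2.

    Raises :class:`DataError` when only one class is present (AUC undefined).
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise DataError("ROC-AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class MinorityPrecision:
    value: float
    n_predicted: int  # minority-class predictions made
    n_correct: int
    defined: bool  # False when no minority predictions were made (0-of-0)
    minority_label: int


def minority_precision(predictions: np.ndarray, labels: np.ndarray) -> MinorityPrecision:
    """Precision of predictions for the less frequent label.

    Returns value 0 with ``defined=False`` when the model never predicts the
    minority class, distinguishing "0 of k wrong" from "nothing attempted".
    On an exactly balanced evaluation set the positive class is taken as the
    minority (logged).
    """
    predictions = np.asarray(predictions).astype(int)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == n_neg:
        logger.info("balanced evaluation set: minority resolved to the positive class")
        minority = 1
    else:
        minority = 1 if n_pos < n_neg else 0
    picked = predictions == minority
    n_predicted = int(picked.sum())
    n_correct = int((picked & (labels == minority)).sum())
    if n_predicted == 0:
        return MinorityPrecision(0.0, 0, 0, False, minority)
    return MinorityPrecision(n_correct / n_predicted, n_predicted, n_correct, True, minority)


@dataclass
class ThresholdCurve:
    """Retained accuracy and coverage as the uncertainty threshold sweeps up."""

    thresholds: list[float]
    accuracy_at: list[Optional[float]]  # None where nothing is retained
    coverage_at: list[float]
    accuracy_reject_as_error: list[float]  # alternative denominator

    def as_dict(self) -> dict:
        return {
            "thresholds": self.thresholds,
            "accuracy_at": self.accuracy_at,
            "coverage_at": self.coverage_at,
            "accuracy_reject_as_error": self.accuracy_reject_as_error,
        }


def threshold_curve(
    outputs: Sequence[EvidentialOutput],
    labels: np.ndarray,
    thresholds: Sequence[float],
) -> ThresholdCurve:
    """Accuracy among predictions with u <= threshold, per threshold.

    Retention is inclusive (u <= t).  Coverage is monotone nondecreasing in
    the threshold; at t=1.0 everything is retained and the retained accuracy
    equals the plain accuracy.
    """
    labels = np.asarray(labels).astype(int)
    u = np.array([o.uncertainty for o in outputs])
    pred = np.array([o.predicted_class for o in outputs])
    correct = pred == labels
    thresholds = sorted(float(t) for t in thresholds)
    acc: list[Optional[float]] = []
    cov: list[float] = []
    acc_rej: list[float] = []
    n = len(outputs)
    for t in thresholds:
        keep = u <= t
        cov.append(float(keep.mean()) if n else 0.0)
        acc.append(float(correct[keep].mean()) if keep.any() else None)
        acc_rej.append(float((correct & keep).sum() / n) if n else 0.0)
    return ThresholdCurve(thresholds, acc, cov, acc_rej)


def evaluation_report(
    per_task: dict[str, tuple[Sequence[EvidentialOutput], np.ndarray]],
    thresholds: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 1.0),
    avuc_u_threshold: float = 0.5,
    include_records: bool = True,
) -> dict:
    """Assemble the JSON evaluation report over completed meta-test tasks.

    Per task: ROC-AUC (positive-class Dirichlet probability as the score),
    minority precision at the argmax prediction, the threshold curve, AvUC
    counts and optionally the per-molecule evidence records.  Averages are
    unweighted means over tasks.
    """
    if not per_task:
        raise DataError("evaluation_report needs at least one completed task")
    tasks_out: dict[str, dict] = {}
    aucs, precisions = [], []
    for task_id, (outputs, labels) in per_task.items():
        labels = np.asarray(labels).astype(int)
        scores = np.array([o.probs[1] for o in outputs])
        pred = np.array([o.predicted_class for o in outputs])
        u = np.array([o.uncertainty for o in outputs])
        conf = np.array([o.confidence for o in outputs])
        try:
            auc = roc_auc(scores, labels)
            aucs.append(auc)
        except DataError:
            auc = None
        mp = minority_precision(pred, labels)
        precisions.append(mp.value)
        counts = avuc_counts(conf, u, pred == labels, avuc_u_threshold)
        entry = {
            "roc_auc": auc,
            "minority_precision": mp.value,
            "minority_precision_defined": mp.defined,
            "minority_label": mp.minority_label,
            "threshold_curve": threshold_curve(outputs, labels, thresholds).as_dict(),
            "avuc_counts": {
                "n_ac": counts.n_ac, "n_au": counts.n_au,
                "n_ic": counts.n_ic, "n_iu": counts.n_iu,
            },
            "avuc": counts.avuc,
            "n_queries": int(len(labels)),
        }
        if include_records:
            entry["molecules"] = [
                {**o.to_record(), "label": int(y)} for o, y in zip(outputs, labels)
            ]
        tasks_out[task_id] = entry
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tasks": tasks_out,
        "mean_roc_auc": float(np.mean(aucs)) if aucs else None,
        "mean_minority_precision": float(np.mean(precisions)),
        "thresholds": [float(t) for t in sorted(thresholds)],
    }


def threshold_curve_csv(curve: ThresholdCurve, path) -> None:
    """Export a threshold curve as CSV for plotting."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["threshold", "coverage", "accuracy_retained", "accuracy_reject_as_error"])
        for t, c, a, ar in zip(
            curve.thresholds, curve.coverage_at, curve.accuracy_at, curve.accuracy_reject_as_error
        ):
            w.writerow([t, c, "" if a is None else a, ar])
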