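"""Evaluation metrics: thresholding, overlap scores, and label reports.

Probability maps are binarized at a fixed threshold (default 0.65,
boundary inclusive) before scoring.  IoU is the standard Jaccard index
``|A∩B| / |A∪B|``; Dice is ``2|A∩B| / (|A|+|B|)``.  Both are smoothed so
that a correctly predicted all-background image (tumor-free case) scores
a perfect 1.0.  Label-level precision/recall/F1 delegate to scikit-learn;
multi-class reports are macro-averaged.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from math import nan

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix as _sk_confusion,
    precision_recall_fscore_support,
)

__all__ = [
    "MetricsRecord",
    "binarize",
    "iou_score",
    "dice_score",
    "classification_report",
    "confusion_matrix",
    "write_metrics_csv",
    "write_confusion_json",
]


@dataclass
class MetricsRecord:
    """One row of evaluation output; unavailable fields stay NaN."""

    iou: float = nan
    dice: float = nan
    f1: float = nan
    precision: float = nan
    recall: float = nan
    accuracy: float = nan
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("extra")
        d.update(self.extra)
        return d


def binarize(probmap, tau: float = 0.65) -> np.ndarray:
    """Threshold a probability map; a pixel is foreground iff value >= tau."""
    if not 0.0 < tau < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {tau}")
    p = np.asarray(probmap, dtype=np.float64)
    return (p >= tau).astype(np.uint8)


def _check_binary(a, name):
    arr = np.asarray(a)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(np.float64)


def iou_score(pred, target, eps: float = 1e-6, form: str = "jaccard") -> float:
    """Jaccard index of two binary masks (both-empty -> 1 by smoothing).

    ``form='printed'`` divides the intersection by the plain sum of the two
    masks instead of the union (an alternative normalisation equal to half
    the Dice coefficient); the default is the standard Jaccard index,
    consistent with the IoU loss.
    """
    p = _check_binary(pred, "pred")
    g = _check_binary(target, "target")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    inter = float((p * g).sum())
    if form == "jaccard":
        denom = float(p.sum() + g.sum() - inter)
    elif form == "printed":
        denom = float(p.sum() + g.sum())
    else:
        raise ValueError(f"unknown IoU form: {form!r}")
    return (inter + eps) / (denom + eps)


def dice_score(pred, target, eps: float = 1e-6) -> float:
    """Dice coefficient of two binary masks (both-empty -> 1 by smoothing)."""
    p = _check_binary(pred, "pred")
    g = _check_binary(target, "target")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    inter = float((p * g).sum())
    total = float(p.sum() + g.sum())
    return (2.0 * inter + eps) / (total + eps)


def classification_report(pred_labels, true_labels) -> MetricsRecord:
    """Precision/recall/F1/accuracy for binary or multi-class labels.

    Binary labels use the positive class (1); three or more classes are
    macro-averaged.
    """
    yp = np.asarray(pred_labels)
    yt = np.asarray(true_labels)
    if yp.shape != yt.shape:
        raise ValueError("pred and true label sequences differ in length")
    if yp.size == 0:
        raise ValueError("empty label sequences")
    classes = np.union1d(yp, yt)
    average = "binary" if np.isin(classes, (0, 1)).all() else "macro"
    prec, rec, f1, _ = precision_recall_fscore_support(
        yt, yp, average=average, zero_division=0)
    return MetricsRecord(
        f1=float(f1), precision=float(prec), recall=float(rec),
        accuracy=float(accuracy_score(yt, yp)))


def confusion_matrix(pred_labels, true_labels, n_classes: int) -> np.ndarray:
    """Count grid: entry (i, j) = true class i predicted as class j."""
    yp = np.asarray(pred_labels)
    yt = np.asarray(true_labels)
    if yp.shape != yt.shape:
        raise ValueError("pred and true label sequences differ in length")
    for arr, name in ((yp, "pred"), (yt, "true")):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} labels outside [0, {n_classes})")
    return _sk_confusion(yt, yp, labels=np.arange(n_classes))


# ---------------------------------------------------------------------------
# writers

CSV_HEADER = ["id", "view", "iou", "dice", "f1", "precision", "recall",
              "accuracy"]


def write_metrics_csv(rows: list[dict], path) -> None:
    """One row per image plus any summary rows; NaN fields left blank."""
    with open(path, "w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=CSV_HEADER, extrasaction="ignore")
        wr.writeheader()
        for row in rows:
            clean = {k: ("" if isinstance(v, float) and np.isnan(v) else v)
                     for k, v in row.items()}
            wr.writerow(clean)


def write_confusion_json(matrix: np.ndarray, path, labels=None) -> None:
    payload = {"labels": list(labels) if labels is not None else
               list(range(matrix.shape[0])),
               "matrix": np.asarray(matrix).astype(int).tolist()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
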