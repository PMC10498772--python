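"""Evaluation metrics and the Dice loss for binary lesion segmentation.

The four metrics are computed from per-pixel confusion counts exactly as
the definitions this package adopts print them:

    sensitivity = TP / (TP + FP)
    specificity = TN / (FP + TN)
    dice        = 2*TP / (2*TP + FN + FP)
    iou         = TP / (TP + FN + FP)

Note the sensitivity definition divides by TP+FP — the quantity
conventionally called *precision*.  It is kept as the default so that
reported numbers match the definition they were reported under; pass
``standard=True`` for the conventional TP/(TP+FN) recall.

The identity ``iou == dice / (2 - dice)`` holds for every confusion
table and is exercised in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "sensitivity",
    "specificity",
    "dice_coefficient",
    "iou",
    "dice_loss",
    "evaluate_all",
    "format_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-pixel agreement counts between a prediction and ground truth.

    tp: lesion pixels predicted lesion; tn: background predicted
    background; fp: background predicted lesion; fn: lesion predicted
    background.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _validate_binary(arr, name):
    a = np.asarray(arr)
    vals = np.unique(a)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be strictly binary (0/1), found values {vals[:8]}")
    return a.astype(np.int64)


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Count TP/TN/FP/FN between two binary masks of identical shape."""
    p = np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    p = _validate_binary(p, "pred")
    t = _validate_binary(t, "truth")
    tp = int(np.sum((p == 1) & (t == 1)))
    tn = int(np.sum((p == 0) & (t == 0)))
    fp = int(np.sum((p == 1) & (t == 0)))
    fn = int(np.sum((p == 0) & (t == 1)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num, den, what):
    if den == 0:
        warnings.warn(
            f"{what}: denominator is zero (degenerate case); returning 1.0 "
            "(perfect agreement on emptiness convention)",
            RuntimeWarning,
            stacklevel=3,
        )
        return 1.0
    return num / den


def sensitivity(c: ConfusionCounts, standard: bool = False) -> float:
    """TP/(TP+FP) by default; ``standard=True`` gives recall TP/(TP+FN)."""
    if standard:
        return _ratio(c.tp, c.tp + c.fn, "sensitivity (standard)")
    return _ratio(c.tp, c.tp + c.fp, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    """TN/(FP+TN)."""
    return _ratio(c.tn, c.fp + c.tn, "specificity")


def dice_coefficient(c: ConfusionCounts) -> float:
    """2*TP/(2*TP+FN+FP)."""
    return _ratio(2 * c.tp, 2 * c.tp + c.fn + c.fp, "dice")


def iou(c: ConfusionCounts) -> float:
    """TP/(TP+FN+FP)."""
    return _ratio(c.tp, c.tp + c.fn + c.fp, "iou")


def dice_loss(pred, truth, eps: float = 1e-6) -> float:
    """Soft Dice loss between a probability map and a binary mask.

    1 - (2*sum(y*y_hat) + eps) / (sum(y^2) + sum(y_hat^2) + eps).

    ``eps`` (default 1e-6) keeps the loss defined when both maps are
    empty; with eps=0 that degenerate case returns 0.0 with a warning.
    This is the plain-number counterpart of
    :func:`pdcnet.autodiff.soft_dice_loss`, which is used for training.
    """
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("pred values must lie in [0, 1]")
    _validate_binary(t, "truth")
    num = 2.0 * float(np.sum(t * p)) + eps
    den = float(np.sum(t * t) + np.sum(p * p)) + eps
    if den == 0.0:
        warnings.warn(
            "dice_loss: both maps empty with eps=0; returning 0.0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return 1.0 - num / den


@dataclass(frozen=True)
class MetricReport:
    sensitivity: float
    specificity: float
    dice: float
    iou: float
    counts: ConfusionCounts

    def as_dict(self):
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "dice": self.dice,
            "iou": self.iou,
        }


def evaluate_all(pred, truth, threshold: float = 0.5,
                 standard_sensitivity: bool = False) -> MetricReport:
    """Binarize a probability map at ``threshold`` and compute all metrics."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    p = np.asarray(pred, dtype=np.float64)
    binary = (p >= threshold).astype(np.int64)
    c = confusion_counts(binary, truth)
    return MetricReport(
        sensitivity=sensitivity(c, standard=standard_sensitivity),
        specificity=specificity(c),
        dice=dice_coefficient(c),
        iou=iou(c),
        counts=c,
    )


def format_report(report: MetricReport) -> str:
    """Flat key/value text record, values to 4 decimals."""
    lines = [f"{k}\t{v:.4f}" for k, v in report.as_dict().items()]
    c = report.counts
    lines.append(f"tp\t{c.tp}")
    lines.append(f"tn\t{c.tn}")
    lines.append(f"fp\t{c.fp}")
    lines.append(f"fn\t{c.fn}")
    return "\n".join(lines) + "\n"
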