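"""Evaluation metrics for segmentation masks and diameter regression.

Segmentation metrics are computed from per-class confusion counts with the
plaque class treated as the positive sample:

* accuracy    = 100 * (TP + TN) / total
* IoU_i       = TP_i / (TP_i + FP_i + FN_i)
* MIoU        = mean IoU over all classes (background included)
* IoU_fg      = mean IoU over non-background classes only
* Dice        = 100 * 2 TP / (2 TP + FP + FN)

A class absent from both prediction and truth has vacuously perfect
agreement and contributes IoU = 1; two empty masks give Dice = 100 by the
same convention.  Regression quality is summarized by MSE (mm^2), MAE (mm)
and the coefficient of determination R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "SegMetrics",
    "RegMetrics",
    "confusion",
    "accuracy",
    "per_class_iou",
    "miou",
    "iou_excluding_background",
    "dice",
    "seg_metrics",
    "regression_metrics",
]


@dataclass
class ConfusionCounts:
    """Pixel-level confusion counts; ``per_class`` holds one (TP, FP, FN)
    triple per class label for the multi-class IoU variants."""

    tp: int
    fp: int
    tn: int
    fn: int
    num_classes: int = 2
    per_class: tuple[tuple[int, int, int], ...] = ()

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if self.num_classes != other.num_classes:
            raise ValueError("class counts differ")
        pc = tuple(
            (a[0] + b[0], a[1] + b[1], a[2] + b[2])
            for a, b in zip(self.per_class, other.per_class)
        )
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn,
                               self.num_classes, pc)


@dataclass
class SegMetrics:
    accuracy_pct: float
    miou_pct: float
    iou_fg_pct: float
    dice_pct: float


@dataclass
class RegMetrics:
    mse: float
    mae: float
    r2: float | None


def confusion(pred_mask: np.ndarray, true_mask: np.ndarray,
              num_classes: int = 2) -> ConfusionCounts:
    """Exact pixel confusion counts; class 0 is background, others positive.

    For ``num_classes == 2`` the scalar TP/FP/TN/FN refer to the plaque
    class; the per-class triples cover every label for MIoU.
    """
    pred = np.asarray(pred_mask)
    true = np.asarray(true_mask)
    if pred.shape != true.shape:
        raise ValueError("mask shapes differ")
    for m in (pred, true):
        if m.min() < 0 or m.max() >= num_classes:
            raise ValueError(f"labels must lie in [0, {num_classes})")
    pc = []
    for c in range(num_classes):
        p = pred == c
        t = true == c
        tp_c = int(np.count_nonzero(p & t))
        fp_c = int(np.count_nonzero(p & ~t))
        fn_c = int(np.count_nonzero(~p & t))
        pc.append((tp_c, fp_c, fn_c))
    p = pred != 0
    t = true != 0
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn, num_classes, tuple(pc))


def accuracy(counts: ConfusionCounts) -> float:
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    return 100.0 * (counts.tp + counts.tn) / counts.total


def per_class_iou(counts: ConfusionCounts) -> list[float]:
    ious = []
    for tp, fp, fn in counts.per_class:
        denom = tp + fp + fn
        ious.append(1.0 if denom == 0 else tp / denom)
    return ious


def miou(counts: ConfusionCounts) -> float:
    """Mean IoU over all classes, background included, in percent."""
    return 100.0 * float(np.mean(per_class_iou(counts)))


def iou_excluding_background(counts: ConfusionCounts) -> float:
    """Mean IoU over the non-background classes only, in percent."""
    ious = per_class_iou(counts)[1:]
    if not ious:
        raise ValueError("no foreground class")
    return 100.0 * float(np.mean(ious))


def dice(counts: ConfusionCounts) -> float:
    """Dice similarity of the positive (plaque) class, in percent."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 100.0  # both masks empty: vacuous perfect agreement
    return 100.0 * 2 * counts.tp / denom


def seg_metrics(counts: ConfusionCounts) -> SegMetrics:
    return SegMetrics(
        accuracy_pct=accuracy(counts),
        miou_pct=miou(counts),
        iou_fg_pct=iou_excluding_background(counts),
        dice_pct=dice(counts),
    )


def regression_metrics(pred, truth) -> RegMetrics:
    """MSE, MAE and R^2 of predicted vs. true values.

    R^2 = 1 - SS_res / SS_tot needs variance in the truth; with constant
    truth it is undefined and reported as ``None`` with a warning.
    """
    import warnings

    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    if pred.size == 0:
        raise ValueError("empty input")
    diff = pred - truth
    mse = float(np.mean(diff ** 2))
    mae = float(np.mean(np.abs(diff)))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("truth has zero variance; R^2 undefined", stacklevel=2)
        r2 = None
    else:
        r2 = 1.0 - float(np.sum(diff ** 2)) / ss_tot
    return RegMetrics(mse=mse, mae=mae, r2=r2)
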