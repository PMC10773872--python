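"""Segmentation evaluation: Jaccard and Dice coefficients and mean IoU.

Two Dice forms are provided.  The ``"literal"`` form divides by the
*union* (sum minus intersection), which exceeds 1 at perfect overlap and is
kept only for fidelity with that formulation; the ``"conventional"`` form
divides by the plain sum of the two masks and equals 1 at perfect overlap.
Conventional is the reporting default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "jaccard_coef",
    "dice_coef",
    "confusion_counts",
    "mean_iou",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest pixel confusion table for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def iou(self) -> float:
        denom = self.tp + self.fp + self.fn
        if denom == 0:
            return float("nan")
        return self.tp / denom


def _check_fields(y_true, y_pred):
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("empty input")
    return y_true, y_pred


def jaccard_coef(y_true, y_pred, smooth: float = 1e-5) -> float:
    """(intersection + smooth) / (union + smooth) on soft or hard fields."""
    y_true, y_pred = _check_fields(y_true, y_pred)
    inter = float((y_true * y_pred).sum())
    union = float(y_true.sum() + y_pred.sum() - inter)
    return (inter + smooth) / (union + smooth)


def dice_coef(y_true, y_pred, smooth: float = 1e-5,
              mode: str = "conventional") -> float:
    """Dice coefficient.

    mode="conventional": (2I + smooth) / (sum_true + sum_pred + smooth).
    mode="literal": (2I + smooth) / (union + smooth) where union subtracts
    the intersection — kept for fidelity, > 1 at perfect overlap.
    """
    y_true, y_pred = _check_fields(y_true, y_pred)
    inter = float((y_true * y_pred).sum())
    total = float(y_true.sum() + y_pred.sum())
    if mode == "conventional":
        return (2.0 * inter + smooth) / (total + smooth)
    if mode == "literal":
        return (2.0 * inter + smooth) / (total - inter + smooth)
    raise ValueError("mode must be 'conventional' or 'literal'")


def confusion_counts(y_true, y_pred_labels, n_classes: int = 2
                     ) -> list[ConfusionCounts]:
    """One-vs-rest confusion counts per class from hard label fields."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred_labels)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        vals = np.unique(arr)
        if vals.size and (vals.min() < 0 or vals.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    out = []
    for c in range(n_classes):
        t = y_true == c
        p = y_pred == c
        tp = int(np.sum(t & p))
        fp = int(np.sum(~t & p))
        fn = int(np.sum(t & ~p))
        tn = int(np.sum(~t & ~p))
        out.append(ConfusionCounts(tp, fp, fn, tn))
    return out


def mean_iou(y_true, y_pred_labels, n_classes: int = 2,
             absent_class_iou: float = 1.0) -> tuple[float, list[float]]:
    """Unweighted mean over classes of IoU = TP / (TP + FP + FN).

    A class absent from both fields has an empty one-vs-rest table
    (TP+FP+FN = 0); by the smooth convention it contributes
    ``absent_class_iou`` (default 1.0).
    Returns (overall, per_class).
    """
    y_true = np.asarray(y_true)
    if y_true.size == 0:
        raise ValueError("empty input")
    counts = confusion_counts(y_true, y_pred_labels, n_classes)
    per_class = []
    for cc in counts:
        iou = cc.iou()
        per_class.append(absent_class_iou if np.isnan(iou) else iou)
    return float(np.mean(per_class)), per_class
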