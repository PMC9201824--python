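"""Training objective and evaluation metrics for crop-row segmentation.

The training loss is the sum of pixelwise binary cross-entropy (computed
from logits with log-sum-exp stabilisation) and a soft Dice loss evaluated
on sigmoid probabilities with a small ``smooth`` term (default 0.1) guarding
the empty-empty denominator.  Evaluation uses hard-mask intersection over
union; a crop-row image counts as correctly detected when IoU >= 0.6.

These functions are plain NumPy and are used for reporting; the training
loop differentiates the same formulas through :mod:`cropnav.nn.autograd`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ShapeError, ValidationError

__all__ = [
    "DETECTION_IOU_THRESHOLD",
    "PixelPrediction",
    "IoUResult",
    "EvalReport",
    "sigmoid",
    "bce_loss",
    "dice_loss",
    "bce_dice_loss",
    "iou",
    "detection_accuracy",
]

#: An image's crop rows count as correctly detected at or above this IoU.
DETECTION_IOU_THRESHOLD = 0.6


@dataclass(frozen=True)
class PixelPrediction:
    """Per-pixel logits paired with a binary ground-truth mask."""

    logits: np.ndarray
    target: np.ndarray

    def __post_init__(self):
        logits = np.asarray(self.logits, dtype=np.float64)
        target = np.asarray(self.target)
        if logits.shape != target.shape:
            raise ShapeError(
                f"logits shape {logits.shape} != target shape {target.shape}"
            )
        if not np.isin(target, (0, 1)).all():
            raise ValidationError("target must be binary (0/1)")
        object.__setattr__(self, "logits", logits)
        object.__setattr__(self, "target", target.astype(np.float64))

    @property
    def m(self) -> int:
        return self.logits.size


@dataclass(frozen=True)
class IoUResult:
    """Intersection-over-union plus the derived correct-detection flag."""

    iou: float
    detected: bool

    @classmethod
    def from_iou(cls, value: float) -> "IoUResult":
        return cls(iou=float(value), detected=bool(value >= DETECTION_IOU_THRESHOLD))


def sigmoid(x):
    """Logistic function 1 / (1 + e^-x), overflow-safe for any real input."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def bce_loss(pred: PixelPrediction) -> float:
    """Mean binary cross-entropy of sigmoid(logits) against the binary target."""
    x, y = pred.logits, pred.target
    per_pixel = np.maximum(x, 0.0) - x * y + np.log1p(np.exp(-np.abs(x)))
    return float(per_pixel.mean())


def dice_loss(pred_probs: np.ndarray, target: np.ndarray, smooth: float = 0.1) -> float:
    """Soft Dice loss 1 - (2|Y∩Yhat| + smooth)/(|Y| + |Yhat| + smooth)."""
    if smooth < 0:
        raise ParameterError("smooth must be non-negative")
    p = np.asarray(pred_probs, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    if p.shape != y.shape:
        raise ShapeError(f"prediction shape {p.shape} != target shape {y.shape}")
    inter = float((p * y).sum())
    return 1.0 - (2.0 * inter + smooth) / (float(p.sum()) + float(y.sum()) + smooth)


def bce_dice_loss(pred: PixelPrediction, smooth: float = 0.1) -> float:
    """Combined objective: BCE on logits plus soft Dice on sigmoid(logits)."""
    return bce_loss(pred) + dice_loss(sigmoid(pred.logits), pred.target, smooth=smooth)


def iou(pred_mask: np.ndarray, true_mask: np.ndarray) -> IoUResult:
    """Hard-mask intersection over union; empty vs empty is defined as 1.0."""
    p = np.asarray(pred_mask)
    t = np.asarray(true_mask)
    if p.shape != t.shape:
        raise ShapeError(f"mask shapes differ: {p.shape} vs {t.shape}")
    for name, m in (("pred_mask", p), ("true_mask", t)):
        if not np.isin(m, (0, 1)).all():
            raise ValidationError(f"{name} must be binary (0/1)")
    p = p.astype(bool)
    t = t.astype(bool)
    union = np.logical_or(p, t).sum()
    if union == 0:
        return IoUResult.from_iou(1.0)
    inter = np.logical_and(p, t).sum()
    return IoUResult.from_iou(inter / union)


def detection_accuracy(results: list[IoUResult]) -> float:
    """Percentage of images whose crop rows were correctly detected."""
    if not results:
        raise ValidationError("detection_accuracy requires a non-empty result list")
    return 100.0 * sum(r.detected for r in results) / len(results)


@dataclass
class EvalReport:
    """Aggregate segmentation evaluation over a dataset."""

    per_image_iou: list[float] = field(default_factory=list)
    detected: list[bool] = field(default_factory=list)
    mean_iou: float = float("nan")
    detection_accuracy_pct: float = float("nan")

    @classmethod
    def from_results(cls, results: list[IoUResult]) -> "EvalReport":
        return cls(
            per_image_iou=[r.iou for r in results],
            detected=[r.detected for r in results],
            mean_iou=float(np.mean([r.iou for r in results])),
            detection_accuracy_pct=detection_accuracy(results),
        )

    def to_dict(self) -> dict:
        return {
            "per_image_iou": list(map(float, self.per_image_iou)),
            "detected": list(map(bool, self.detected)),
            "mean_iou": float(self.mean_iou),
            "detection_accuracy_pct": float(self.detection_accuracy_pct),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(
            per_image_iou=list(d["per_image_iou"]),
            detected=list(d["detected"]),
            mean_iou=d["mean_iou"],
            detection_accuracy_pct=d["detection_accuracy_pct"],
        )
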