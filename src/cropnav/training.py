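"""Training loop, augmentation and evaluation for the segmentation networks.

The objective is the combined BCE + soft-Dice loss on the crop logit,
minimised with Adam (initial learning rate 1e-4, step decay by 0.1 at
configurable epochs, batch size 8 by default).  Augmentation applies random
horizontal flip, vertical flip and 90-degree rotation, each independently
with probability 0.5, to image, mask and ground-truth lines consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, TrainingError, ValidationError
from .losses import EvalReport, IoUResult, iou
from .models import NetworkHandle, crop_logit, normalize_image, segment_image
from .nn import autograd as ag
from .nn.optim import Adam
from .synthetic import FieldSample, GroundTruthLine

__all__ = ["TrainConfig", "TrainReport", "augment", "train", "evaluate"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of a training run (defaults follow the study protocol)."""

    learning_rate: float = 1e-4
    lr_decay: float = 0.1
    epochs: int = 85
    batch_size: int = 8
    optimizer: str = "adam"
    augment_prob: float = 0.5
    input_size: int = 512
    seed: int = 0
    decay_schedule: tuple[int, ...] = (60,)
    smooth: float = 0.1

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")
        if not 0.0 <= self.augment_prob <= 1.0:
            raise ParameterError("augment_prob must lie in [0, 1]")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ParameterError("only the adam optimizer is supported")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ParameterError("lr_decay must lie in (0, 1]")
        if self.smooth < 0:
            raise ParameterError("smooth must be non-negative")


@dataclass
class TrainReport:
    """Per-epoch training losses plus final held-out metrics."""

    loss_curve: list[float] = field(default_factory=list)
    val_iou_curve: list[float] = field(default_factory=list)
    best_epoch: int = 0
    final_metrics: EvalReport | None = None

    def to_dict(self) -> dict:
        return {
            "loss_curve": list(map(float, self.loss_curve)),
            "val_iou_curve": list(map(float, self.val_iou_curve)),
            "best_epoch": int(self.best_epoch),
            "final_metrics": self.final_metrics.to_dict() if self.final_metrics else None,
        }


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def _reparam_lines(endpoints: list[tuple[np.ndarray, np.ndarray]], height: int) -> list[GroundTruthLine]:
    lines = []
    for a, b in endpoints:
        dy = b[1] - a[1]
        if abs(dy) < 1e-9:  # line became horizontal; abscissas blow up but stay finite
            dy = 1e-9 if dy >= 0 else -1e-9
        t0 = (0.0 - a[1]) / dy
        t1 = (height - 1.0 - a[1]) / dy
        x0 = float(np.clip(a[0] + t0 * (b[0] - a[0]), -1e9, 1e9))
        x1 = float(np.clip(a[0] + t1 * (b[0] - a[0]), -1e9, 1e9))
        lines.append(GroundTruthLine(x0=x0, x1=x1))
    return lines


def augment(sample: FieldSample, rng: np.random.Generator, p: float = 0.5) -> FieldSample:
    """Random horizontal/vertical flip and 90-degree rotation, each with probability ``p``.

    Image, mask and ground-truth lines are transformed consistently; the
    rotation branch requires a square sample and picks +90 or -90 degrees
    uniformly.
    """
    h, w = sample.mask.shape
    image, mask = sample.image, sample.mask
    endpoints = [
        (np.array([line.x0, 0.0]), np.array([line.x1, h - 1.0])) for line in sample.gt_lines
    ]
    draws = rng.random(3)

    if draws[0] < p:  # horizontal flip
        image = image[:, ::-1]
        mask = mask[:, ::-1]
        endpoints = [(np.array([w - 1 - a[0], a[1]]), np.array([w - 1 - b[0], b[1]])) for a, b in endpoints]
    if draws[1] < p:  # vertical flip
        image = image[::-1]
        mask = mask[::-1]
        endpoints = [(np.array([a[0], h - 1 - a[1]]), np.array([b[0], h - 1 - b[1]])) for a, b in endpoints]
    if draws[2] < p:  # 90-degree rotation, direction uniform in {+90, -90}
        if h != w:
            raise ParameterError("90-degree rotation requires square samples")
        k = 1 if rng.random() < 0.5 else 3
        image = np.rot90(image, k=k, axes=(0, 1))
        mask = np.rot90(mask, k=k)
        if k == 1:  # counter-clockwise: (x, y) -> (y, W-1-x)
            endpoints = [
                (np.array([a[1], w - 1 - a[0]]), np.array([b[1], w - 1 - b[0]]))
                for a, b in endpoints
            ]
        else:  # clockwise: (x, y) -> (H-1-y, x)
            endpoints = [
                (np.array([h - 1 - a[1], a[0]]), np.array([h - 1 - b[1], b[0]]))
                for a, b in endpoints
            ]
    return FieldSample(
        image=np.ascontiguousarray(image),
        mask=np.ascontiguousarray(mask),
        gt_lines=_reparam_lines(endpoints, image.shape[0]),
    )


# ---------------------------------------------------------------------------
# Training and evaluation
# ---------------------------------------------------------------------------


def _batch_arrays(samples: list[FieldSample], dtype) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([normalize_image(s.image, dtype=dtype) for s in samples])
    y = np.stack([s.mask for s in samples]).astype(dtype)
    return x, y


def train(
    net: NetworkHandle,
    train_set: list[FieldSample],
    val_set: list[FieldSample],
    config: TrainConfig = TrainConfig(),
) -> TrainReport:
    """Minimise BCE + Dice over the training set; returns the loss curve and
    final held-out metrics.  Deterministic for a fixed config seed."""
    config.validate()
    if not train_set or not val_set:
        raise ValidationError("train and validation sets must be non-empty")
    ss = np.random.SeedSequence(config.seed)
    rng_shuffle, rng_augment, rng_dropout = (np.random.default_rng(s) for s in ss.spawn(3))
    net.net.rng_box.generator = rng_dropout
    net.train()
    dtype = next(net.net.parameters()).data.dtype
    params = list(net.net.parameters())
    opt = Adam(params, lr=config.learning_rate)

    report = TrainReport()
    n = len(train_set)
    for epoch in range(config.epochs):
        if epoch in config.decay_schedule:
            opt.lr *= config.lr_decay
        order = rng_shuffle.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            batch = [train_set[i] for i in order[start : start + config.batch_size]]
            if config.augment_prob > 0:
                batch = [augment(s, rng_augment, p=config.augment_prob) for s in batch]
            x, y = _batch_arrays(batch, dtype)
            net.train()
            scores = net(x)
            logit = crop_logit(scores)
            loss = ag.add(
                ag.bce_with_logits_mean(logit, y),
                ag.soft_dice_loss(ag.sigmoid(logit), y, smooth=config.smooth),
            )
            value = float(loss.data)
            if not np.isfinite(value):
                raise TrainingError(f"training diverged: non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(value)
        report.loss_curve.append(float(np.mean(epoch_losses)))
        report.val_iou_curve.append(evaluate(net, val_set).mean_iou)
    report.best_epoch = int(np.argmax(report.val_iou_curve)) if report.val_iou_curve else 0
    report.final_metrics = evaluate(net, val_set)
    return report


def evaluate(net: NetworkHandle, data: list[FieldSample]) -> EvalReport:
    """Per-image IoU of thresholded predictions plus aggregate detection accuracy."""
    if not data:
        raise ValidationError("evaluate requires a non-empty dataset")
    results: list[IoUResult] = []
    for sample in data:
        prob = segment_image(net, sample.image)
        pred_mask = (prob >= 0.5).astype(np.uint8)
        results.append(iou(pred_mask, sample.mask))
    return EvalReport.from_results(results)
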