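"""Closed-form, oracle and invariance tests for the losses and metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cropnav import losses
from cropnav.errors import ParameterError, ShapeError, ValidationError
from cropnav.losses import (
    IoUResult,
    PixelPrediction,
    bce_dice_loss,
    bce_loss,
    detection_accuracy,
    dice_loss,
    iou,
    sigmoid,
)


class TestSigmoid:
    def test_values(self):
        assert sigmoid(0.0) == pytest.approx(0.5)
        assert sigmoid(2.0) == pytest.approx(0.8807970779778823, abs=1e-12)

    @given(st.floats(-700, 700))
    @settings(derandomize=True, deadline=None)
    def test_symmetry_and_range(self, x):
        assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= sigmoid(x) <= 1.0


class TestBCE:
    def test_zero_logits_give_ln2(self):
        target = (np.arange(16).reshape(4, 4) % 2).astype(float)
        pred = PixelPrediction(logits=np.zeros((4, 4)), target=target)
        assert bce_loss(pred) == pytest.approx(math.log(2.0), abs=1e-12)

    def test_saturated_prediction_drives_loss_to_zero(self):
        target = np.array([[1.0, 0.0], [0.0, 1.0]])
        logits = np.where(target == 1, 1e4, -1e4)
        assert bce_loss(PixelPrediction(logits=logits, target=target)) == pytest.approx(0.0, abs=1e-10)

    def test_matches_scalar_by_scalar_computation(self):
        """2x2 oracle: independent per-pixel evaluation of the definition."""
        y = np.array([[1.0, 0.0], [1.0, 0.0]])
        yhat = np.array([[1.0, -1.0], [0.5, -0.5]])
        expected = -np.mean(
            [
                math.log(1 / (1 + math.exp(-1.0))),
                math.log(1 - 1 / (1 + math.exp(1.0))),
                math.log(1 / (1 + math.exp(-0.5))),
                math.log(1 - 1 / (1 + math.exp(0.5))),
            ]
        )
        assert bce_loss(PixelPrediction(logits=yhat, target=y)) == pytest.approx(expected, abs=1e-12)

    def test_non_binary_target_rejected(self):
        with pytest.raises(ValidationError):
            PixelPrediction(logits=np.zeros((2, 2)), target=np.full((2, 2), 0.5))


class TestDice:
    def test_perfect_overlap_is_zero(self):
        y = np.ones((5, 5))
        assert dice_loss(y, y, smooth=0.1) == pytest.approx(0.0)

    def test_empty_empty_is_zero_thanks_to_smooth(self):
        z = np.zeros((3, 3))
        assert dice_loss(z, z, smooth=0.1) == pytest.approx(0.0)

    def test_hand_counted_partial_overlap(self):
        target = np.zeros((4, 4))
        target[0, :4] = 1  # |Y| = 4
        pred = np.zeros((4, 4))
        pred[0, :2] = 1  # |Yhat| = 2, intersection 2
        expected = 1.0 - (2 * 2 + 0.1) / (4 + 2 + 0.1)
        assert dice_loss(pred, target, smooth=0.1) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.32786885, abs=1e-6)

    def test_negative_smooth_rejected(self):
        with pytest.raises(ParameterError):
            dice_loss(np.ones((2, 2)), np.ones((2, 2)), smooth=-0.1)


class TestBCEDice:
    def test_is_sum_of_components(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(6, 6))
        target = (rng.random((6, 6)) > 0.5).astype(float)
        pred = PixelPrediction(logits=logits, target=target)
        expected = bce_loss(pred) + dice_loss(sigmoid(logits), target)
        assert bce_dice_loss(pred) == pytest.approx(expected, abs=1e-12)

    def test_perfect_saturated_prediction_is_zero(self):
        target = (np.arange(9).reshape(3, 3) % 2).astype(float)
        logits = np.where(target == 1, 1e4, -1e4)
        assert bce_dice_loss(PixelPrediction(logits=logits, target=target)) == pytest.approx(0.0, abs=1e-6)

    def test_decreases_towards_the_target(self):
        """The loss falls monotonically along random-logits -> saturating-logits."""
        rng = np.random.default_rng(1)
        target = (rng.random((8, 8)) > 0.5).astype(float)
        start = rng.normal(scale=0.5, size=(8, 8))
        end = np.where(target == 1, 12.0, -12.0)
        values = [
            bce_dice_loss(PixelPrediction(logits=(1 - t) * start + t * end, target=target))
            for t in np.linspace(0, 1, 9)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_gradient_matches_finite_differences(self):
        """Analytic d(BCE+Dice)/dlogits agrees with central differences to 1e-4."""
        from cropnav.nn import autograd as ag
        from cropnav.nn.autograd import Tensor

        rng = np.random.default_rng(2)
        target = (rng.random((4, 4)) > 0.5).astype(float)
        logits = Tensor(rng.normal(size=(4, 4)), requires_grad=True)

        def value():
            return ag.add(
                ag.bce_with_logits_mean(logits, target),
                ag.soft_dice_loss(ag.sigmoid(logits), target, smooth=0.1),
            )

        value().backward()
        analytic = logits.grad
        eps = 1e-6
        numeric = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                orig = logits.data[i, j]
                logits.data[i, j] = orig + eps
                hi = float(value().data)
                logits.data[i, j] = orig - eps
                lo = float(value().data)
                logits.data[i, j] = orig
                numeric[i, j] = (hi - lo) / (2 * eps)
        assert np.abs(analytic - numeric).max() / np.abs(numeric).max() < 1e-4


class TestIoU:
    def test_identical_and_disjoint_masks(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        a[:, :2] = 1
        same = iou(a, a)
        assert same.iou == 1.0 and same.detected
        b = 1 - a
        disjoint = iou(a, b)
        assert disjoint.iou == 0.0 and not disjoint.detected

    def test_half_overlap_not_detected_at_threshold(self):
        full = np.ones((8, 8), dtype=np.uint8)
        half = np.zeros((8, 8), dtype=np.uint8)
        half[:, :4] = 1
        result = iou(half, full)
        assert result.iou == pytest.approx(0.5)
        assert not result.detected

    def test_empty_empty_defined_as_one(self):
        z = np.zeros((3, 3), dtype=np.uint8)
        assert iou(z, z).iou == 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeError):
            iou(np.zeros((2, 2), dtype=np.uint8), np.zeros((3, 3), dtype=np.uint8))

    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_symmetry_and_geometric_invariance(self, bits_a, bits_b):
        a = np.array([(bits_a >> k) & 1 for k in range(16)], dtype=np.uint8).reshape(4, 4)
        b = np.array([(bits_b >> k) & 1 for k in range(16)], dtype=np.uint8).reshape(4, 4)
        base = iou(a, b).iou
        assert iou(b, a).iou == base
        assert iou(a[:, ::-1], b[:, ::-1]).iou == base
        assert iou(a[::-1], b[::-1]).iou == base
        assert iou(np.rot90(a), np.rot90(b)).iou == base


class TestDetectionAccuracy:
    @pytest.mark.parametrize(
        "ious,expected",
        [([0.9, 0.8, 0.61], 100.0), ([0.1, 0.2], 0.0), ([0.9] * 9 + [0.1], 90.0)],
    )
    def test_percentages(self, ious, expected):
        results = [IoUResult.from_iou(v) for v in ious]
        assert detection_accuracy(results) == pytest.approx(expected)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            detection_accuracy([])

    def test_threshold_is_inclusive(self):
        assert IoUResult.from_iou(losses.DETECTION_IOU_THRESHOLD).detected
        assert not IoUResult.from_iou(losses.DETECTION_IOU_THRESHOLD - 1e-9).detected
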