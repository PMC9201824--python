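"""Architecture, parameter-accounting and inference tests for both networks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cropnav import models
from cropnav.errors import ParameterError, ShapeError
from cropnav.models import (
    ArchitectureSpec,
    build_classic_enet,
    build_improved_enet,
    count_trainable_parameters,
    receptive_field_side,
    segment_image,
)


class TestReceptiveField:
    @pytest.mark.parametrize("kernel,dilation,expected", [(3, 1, 3), (3, 2, 5), (3, 4, 9), (5, 1, 5)])
    def test_known_values(self, kernel, dilation, expected):
        assert receptive_field_side(kernel, dilation) == expected

    @given(st.sampled_from([1, 3, 5, 7]), st.integers(1, 8))
    @settings(derandomize=True, deadline=None, max_examples=40)
    def test_matches_kernel_support_enumeration(self, kernel, dilation):
        """Oracle: span of the explicit dilated-tap positions."""
        taps = [dilation * i for i in range(kernel)]
        assert receptive_field_side(kernel, dilation) == taps[-1] - taps[0] + 1

    def test_even_kernel_rejected(self):
        with pytest.raises(ParameterError):
            receptive_field_side(4, 1)
        with pytest.raises(ParameterError):
            receptive_field_side(3, 0)


class TestSpecs:
    def test_improved_stage1_carries_the_replacement_convolutions(self):
        spec = ArchitectureSpec.improved()
        kinds = [(b.kind, b.dilation) for b in spec.stage1]
        assert kinds == [
            ("downsample", 1),
            ("regular", 1),
            ("dilated", 2),
            ("asymmetric", 1),
            ("dilated", 4),
        ]
        assert spec.stage1[3].asym_kernel == 5

    def test_replacement_preserves_module_count(self):
        assert len(ArchitectureSpec.improved().stage1) == len(ArchitectureSpec.classic().stage1)

    def test_stage3_removed_from_improved_but_kept_in_classic(self):
        assert ArchitectureSpec.improved().stage3 == ()
        assert len(ArchitectureSpec.classic().stage3) == 8

    def test_spec_round_trips_through_dict(self):
        spec = ArchitectureSpec.improved(width_multiplier=0.5)
        assert ArchitectureSpec.from_dict(spec.to_dict()) == spec

    def test_invalid_specs_rejected(self):
        with pytest.raises(ParameterError):
            ArchitectureSpec(residual_stream=True, stage1=(), stage2=()).validate()
        bad = ArchitectureSpec.improved().__class__.improved()
        with pytest.raises(ParameterError):
            models.ImprovedENet(ArchitectureSpec.classic())
        with pytest.raises(ParameterError):
            models.ClassicENet(bad)


class TestParameterAccounting:
    def test_single_conv_closed_form(self, rng):
        from cropnav.nn import Conv2d

        conv = Conv2d(3, 16, 3, rng, padding=1, bias=True)
        assert count_trainable_parameters(conv) == 3 * 3 * 3 * 16 + 16

    def test_freezing_a_layer_removes_exactly_its_size(self):
        net = build_improved_enet(ArchitectureSpec.improved(0.25), seed=0)
        total = count_trainable_parameters(net)
        head_w = net.net.head.weight
        head_w.requires_grad = False
        assert count_trainable_parameters(net) == total - head_w.data.size

    def test_improved_is_lighter_than_classic_at_default_widths(self):
        improved = build_improved_enet()
        classic = build_classic_enet()
        assert improved.parameter_count < classic.parameter_count

    def test_width_multiplier_halves_channels_and_reduces_parameters(self):
        full = build_improved_enet(ArchitectureSpec.improved(1.0))
        half = build_improved_enet(ArchitectureSpec.improved(0.5))
        assert half.parameter_count < full.parameter_count
        spec_f, spec_h = full.spec, half.spec
        for base in (spec_f.initial_width, spec_f.stage1_width, spec_f.stage2_width):
            assert spec_h.width(base) == spec_f.width(base) // 2

    def test_rebuilds_with_same_spec_and_seed_are_identical(self):
        a = build_classic_enet(seed=3)
        b = build_classic_enet(seed=3)
        assert a.parameter_count == b.parameter_count
        for (na, pa), (nb, pb) in zip(a.net.named_parameters(), b.net.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)


class TestForwardPass:
    def test_improved_zero_image_gives_finite_two_class_scores(self):
        net = build_improved_enet(ArchitectureSpec.improved(0.25), seed=0)
        out = net(np.zeros((1, 3, 64, 64), dtype=np.float32))
        assert out.shape == (1, 2, 64, 64)
        assert np.isfinite(out.data).all()

    def test_classic_output_matches_input_spatial_shape(self):
        net = build_classic_enet(ArchitectureSpec.classic(0.25), seed=0)
        out = net(np.zeros((1, 3, 64, 64), dtype=np.float32))
        assert out.shape == (1, 2, 64, 64)

    def test_inference_mode_is_deterministic(self, rng):
        net = build_improved_enet(ArchitectureSpec.improved(0.25), seed=0).eval()
        x = rng.normal(size=(1, 3, 64, 64)).astype(np.float32)
        np.testing.assert_array_equal(net(x).data, net(x).data)

    @pytest.mark.parametrize("hw", [(64, 64), (64, 128), (128, 64)])
    def test_resolution_covariance(self, hw):
        net = build_improved_enet(ArchitectureSpec.improved(0.25), seed=0).eval()
        h, w = hw
        assert net(np.zeros((1, 3, h, w), dtype=np.float32)).shape == (1, 2, h, w)

    def test_indivisible_resolution_rejected(self):
        net = build_improved_enet(ArchitectureSpec.improved(0.25), seed=0)
        with pytest.raises(ShapeError):
            net(np.zeros((1, 3, 60, 64), dtype=np.float32))


class TestSegmentImage:
    def test_untrained_network_yields_valid_probabilities(self, small_clean_params):
        from cropnav.synthetic import generate_scene

        sample = generate_scene(small_clean_params, seed=0)
        net = build_improved_enet(ArchitectureSpec.improved(0.25), seed=0)
        prob = segment_image(net, sample.image)
        assert prob.shape == sample.mask.shape
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_segmenting_restores_training_mode_flag(self, small_clean_params):
        from cropnav.synthetic import generate_scene

        sample = generate_scene(small_clean_params, seed=0)
        net = build_improved_enet(ArchitectureSpec.improved(0.25), seed=0)
        net.train()
        segment_image(net, sample.image)
        assert net.net.training


class TestCheckpoints:
    def test_round_trip_preserves_outputs(self, tmp_path, rng):
        net = build_improved_enet(ArchitectureSpec.improved(0.25), seed=4).eval()
        x = rng.normal(size=(1, 3, 64, 64)).astype(np.float32)
        before = net(x).data
        path = models.save_checkpoint(net, tmp_path / "model.npz")
        restored = models.load_checkpoint(path).eval()
        assert restored.spec == net.spec
        np.testing.assert_allclose(restored(x).data, before, rtol=1e-6)

    def test_missing_checkpoint_raises(self, tmp_path):
        from cropnav.errors import CheckpointError

        with pytest.raises(CheckpointError):
            models.load_checkpoint(tmp_path / "nope.npz")
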