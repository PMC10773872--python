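"""Architecture building blocks and network-level contracts."""

import numpy as np
import pytest

from glandseg import nn
from glandseg.models import (
    AttentionGate,
    ForwardConvUnit,
    ModelSpec,
    ResidualUnit,
    build_model,
    predict_patch,
)


def _zero_params(module):
    for p in module.parameters():
        p.data = np.zeros_like(p.data)


class TestForwardConvUnit:
    def test_shape_contract(self):
        rng = np.random.default_rng(0)
        unit = ForwardConvUnit(3, 16, rng)
        out = unit(nn.Tensor(rng.random((1, 64, 64, 3), dtype=np.float32)))
        assert out.shape == (1, 64, 64, 16)

    def test_outputs_non_negative(self):
        rng = np.random.default_rng(1)
        unit = ForwardConvUnit(3, 8, rng)
        out = unit(nn.Tensor(rng.normal(size=(1, 16, 16, 3)).astype(np.float32)))
        assert out.data.min() >= 0

    def test_zero_weights_give_zero_output(self):
        rng = np.random.default_rng(2)
        unit = ForwardConvUnit(3, 8, rng, batch_norm=False)
        _zero_params(unit)
        out = unit(nn.Tensor(rng.random((1, 8, 8, 3), dtype=np.float32)))
        assert np.all(out.data == 0)

    def test_nonpositive_filters_raise(self):
        with pytest.raises(ValueError):
            ForwardConvUnit(3, 0, np.random.default_rng(0))


class TestResidualUnit:
    def test_zeroed_conv_path_is_identity(self):
        rng = np.random.default_rng(3)
        unit = ResidualUnit(8, 8, rng)  # matching channels: identity shortcut
        _zero_params(unit.conv1)
        _zero_params(unit.conv2)
        x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
        out = unit(nn.Tensor(x))
        np.testing.assert_array_equal(out.data, x)

    def test_projection_shortcut_shape(self):
        rng = np.random.default_rng(4)
        unit = ResidualUnit(16, 32, rng)
        out = unit(nn.Tensor(rng.random((1, 32, 32, 16), dtype=np.float32)))
        assert out.shape == (1, 32, 32, 32)
        assert unit.proj is not None

    def test_output_is_sum_of_branches(self):
        rng = np.random.default_rng(5)
        unit = ResidualUnit(8, 8, rng)
        x = nn.Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
        path = unit.conv_path(x).data
        np.testing.assert_allclose(unit(x).data, path + x.data, rtol=1e-6)


class TestAttentionGate:
    def test_forced_passthrough(self):
        """A large psi bias saturates the sigmoid so alpha = 1 and the gate
        passes the skip through unchanged."""
        rng = np.random.default_rng(6)
        gate = AttentionGate(8, 16, rng)
        gate.psi.b.data[:] = 50.0
        skip = rng.random((1, 16, 16, 8)).astype(np.float32)
        g = rng.random((1, 8, 8, 16)).astype(np.float32)
        out = gate(nn.Tensor(skip), nn.Tensor(g))
        np.testing.assert_allclose(out.data, skip, atol=1e-6)

    def test_zero_skip_gives_zero_output(self):
        rng = np.random.default_rng(7)
        gate = AttentionGate(8, 16, rng)
        out = gate(
            nn.Tensor(np.zeros((1, 16, 16, 8), dtype=np.float32)),
            nn.Tensor(rng.random((1, 8, 8, 16)).astype(np.float32)),
        )
        assert np.all(out.data == 0)

    def test_coefficients_stay_in_unit_interval(self):
        rng = np.random.default_rng(8)
        for trial in range(1000):
            gate = AttentionGate(4, 8, rng)
            skip = nn.Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))
            g = nn.Tensor(rng.normal(size=(1, 2, 2, 8)).astype(np.float32))
            alpha = gate.coefficients(skip, g).data
            assert alpha.min() >= 0.0 and alpha.max() <= 1.0

    def test_incompatible_scales_raise(self):
        rng = np.random.default_rng(9)
        gate = AttentionGate(4, 8, rng)
        with pytest.raises(ValueError):
            gate(
                nn.Tensor(np.zeros((1, 8, 8, 4), dtype=np.float32)),
                nn.Tensor(np.zeros((1, 8, 8, 8), dtype=np.float32)),
            )


class TestBuildModel:
    @pytest.mark.parametrize("family", ["unet", "aunet", "arunet"])
    def test_output_field_shape_and_normalization(self, family):
        spec = ModelSpec(family=family, depth=3, base_filters=4,
                         input_size=64, seed=0)
        model = build_model(spec)
        rng = np.random.default_rng(0)
        probs = predict_patch(model, rng.random((64, 64, 3), dtype=np.float32))
        assert probs.shape == (64, 64, 2)
        np.testing.assert_allclose(probs.sum(-1), 1.0, atol=1e-6)

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(family="unet", depth=5, input_size=100)

    def test_seeded_rebuild_is_identical(self):
        spec = ModelSpec(family="arunet", depth=3, base_filters=4,
                         input_size=32, seed=123)
        a, b = build_model(spec), build_model(spec)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_parameter_count_ordering(self):
        counts = {}
        for family in ("unet", "aunet", "arunet"):
            spec = ModelSpec(family=family, depth=3, base_filters=8,
                             input_size=64, seed=0)
            counts[family] = build_model(spec).n_parameters()
        assert counts["arunet"] > counts["aunet"] > counts["unet"]

    def test_predict_patch_size_mismatch_names_expected(self):
        model = build_model(ModelSpec(family="unet", depth=2, base_filters=4,
                                      input_size=32))
        with pytest.raises(ValueError, match="32"):
            predict_patch(model, np.zeros((64, 64, 3), dtype=np.uint8))

    def test_constant_input_gives_near_constant_interior(self):
        """Translation consistency: a constant image maps to a spatially
        constant probability field away from the borders."""
        model = build_model(ModelSpec(family="arunet", depth=3, base_filters=4,
                                      input_size=128, seed=1))
        probs = predict_patch(model, np.full((128, 128, 3), 0.5, dtype=np.float32))
        # the network's receptive field spans ~25 px; stay well clear of it
        interior = probs[40:-40, 40:-40, 1]
        assert interior.max() - interior.min() < 1e-4

    def test_gradients_reach_every_parameter(self):
        """One training step must put a nonzero gradient on each tensor."""
        rng = np.random.default_rng(2)
        for family in ("unet", "aunet", "arunet"):
            model = build_model(ModelSpec(family=family, depth=3,
                                          base_filters=4, input_size=32, seed=0))
            x = rng.random((2, 32, 32, 3), dtype=np.float32)
            out = model.forward(x, training=True)
            target = rng.integers(0, 2, (2, 32, 32)).astype(np.float32)
            from glandseg.losses import total_loss
            total_loss(target, out).backward()
            for p in model.parameters():
                assert p.grad is not None
                assert np.any(p.grad != 0)
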