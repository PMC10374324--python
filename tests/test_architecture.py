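import numpy as np
import pytest

from grapedet import nn
from grapedet.architecture import (ArchitectureSpec, FusionNode, build_model,
                                   fast_normalized_fusion, mish)


class TestMish:
    def test_zero(self):
        assert float(mish(np.array(0.0))) == 0.0

    def test_at_one(self):
        assert float(mish(np.array(1.0))) == pytest.approx(0.8651, abs=5e-5)

    def test_asymptote(self):
        assert float(mish(np.array(20.0))) == pytest.approx(20.0, abs=1e-6)

    def test_large_negative_stable(self):
        assert float(mish(np.array(-500.0))) == pytest.approx(0.0, abs=1e-12)

    def test_definition_on_array(self, rng):
        x = rng.normal(size=32)
        assert np.allclose(mish(x), x * np.tanh(np.log1p(np.exp(x))))


class TestFusionNode:
    def test_weights_nonnegative_and_sum_to_one(self, rng):
        node = FusionNode(3)
        for _ in range(20):
            # raws in the learnable regime (init 1, moved by gradient steps)
            node.raw_weights.data = rng.uniform(0.5, 2.0, size=3).astype(np.float32)
            w = node.normalized_weights().data
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0, abs=1e-4)

    def test_weights_nonnegative_for_negative_raws(self, rng):
        node = FusionNode(3)
        node.raw_weights.data = np.array([-1.0, 2.0, -0.5], dtype=np.float32)
        w = node.normalized_weights().data
        assert np.all(w >= 0)
        assert w[0] == 0 and w[2] == 0

    def test_equal_inputs_pass_through(self, rng):
        node = FusionNode(2)
        x = nn.Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        out = node([x, x])
        assert np.allclose(out.data, x.data, rtol=2e-4, atol=1e-5)

    def test_one_hot_raw_weights(self, rng):
        node = FusionNode(3, epsilon=1e-4)
        node.raw_weights.data = np.array([1.0, 0.0, 0.0], dtype=np.float32)
        inputs = [nn.Tensor(rng.normal(size=(1, 2, 4, 4))) for _ in range(3)]
        out = fast_normalized_fusion(inputs, node)
        assert np.allclose(out.data, inputs[0].data / (1 + 1e-4), rtol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        node = FusionNode(2)
        with pytest.raises(ValueError):
            node([nn.Tensor(np.zeros((1, 2, 4, 4))), nn.Tensor(np.zeros((1, 2, 8, 8)))])

    def test_gradient_reaches_raw_weights(self, rng):
        node = FusionNode(2)
        a = nn.Tensor(rng.normal(size=(1, 2, 3, 3)))
        b = nn.Tensor(rng.normal(size=(1, 2, 3, 3)))
        node([a, b]).sum().backward()
        assert node.raw_weights.grad is not None
        assert np.any(node.raw_weights.grad != 0)


class TestSppAndPooling:
    def test_spatial_size_preserved(self, rng):
        x = nn.Tensor(rng.normal(size=(1, 3, 19, 19)))
        for k in (5, 9, 13):
            assert nn.maxpool_same(x, k).shape == x.shape

    def test_constant_input_constant_output(self):
        x = nn.Tensor(np.full((1, 2, 9, 9), 4.5))
        for k in (5, 9, 13):
            assert np.all(nn.maxpool_same(x, k).data == 4.5)

    def test_concat_multiplies_channels(self, rng):
        x = nn.Tensor(rng.normal(size=(1, 6, 5, 5)))
        cat = nn.concat([x, x, x, x], axis=1)
        assert cat.shape == (1, 24, 5, 5)


class TestTinyModel:
    def test_head_channel_formula(self, tiny_spec):
        assert tiny_spec.head_channels == 18            # 3 * (5 + 1)
        five = ArchitectureSpec(input_size=128, num_classes=5)
        assert five.head_channels == 30                 # 3 * (5 + 5)

    def test_three_heads_with_grid_sizes(self, tiny_model, tiny_spec, rng):
        x = rng.random((1, 3, 128, 128), dtype=np.float32)
        outs = tiny_model(x)
        assert [o.shape for o in outs] == [(1, 18, 16, 16), (1, 18, 8, 8), (1, 18, 4, 4)]

    def test_eval_forward_deterministic(self, tiny_model, rng):
        x = rng.random((1, 3, 128, 128), dtype=np.float32)
        a = tiny_model(x)
        b = tiny_model(x)
        for u, v in zip(a, b):
            assert np.array_equal(u.data, v.data)

    def test_input_not_multiple_of_32_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model(np.zeros((1, 3, 100, 100), dtype=np.float32))
        with pytest.raises(ValueError):
            ArchitectureSpec(input_size=100)

    def test_stride_arithmetic_at_512(self):
        spec = ArchitectureSpec(input_size=512, num_classes=1,
                                stage_repeats=(1, 1, 1, 1, 1), width_mult=0.125)
        model = build_model(spec, seed=0).eval()
        with nn.no_grad():
            p3, p4, p5 = model.backbone(nn.Tensor(np.zeros((1, 3, 512, 512), dtype=np.float32)))
        assert p3.shape[2:] == (64, 64)    # /8
        assert p4.shape[2:] == (32, 32)    # /16
        assert p5.shape[2:] == (16, 16)    # /32

    def test_simam_toggle_keeps_parameter_count(self, tiny_spec):
        with_am = build_model(tiny_spec, seed=0)
        spec_off = ArchitectureSpec(input_size=128, num_classes=1,
                                    stage_repeats=(1, 1, 1, 1, 1), width_mult=0.25,
                                    attention=False)
        without = build_model(spec_off, seed=0)
        assert with_am.num_parameters() == without.num_parameters()
        # ... but the outputs differ (SimAM actually does something)
        x = np.random.default_rng(1).random((1, 3, 128, 128), dtype=np.float32)
        a = with_am.eval()(x)[0].data
        b = without.eval()(x)[0].data
        assert not np.allclose(a, b)


@pytest.fixture(scope="module")
def full_model():
    """Full-width 608-input detector (shared across the shape tests)."""
    return build_model(ArchitectureSpec(), seed=0).eval()


class TestFullSizeArchitecture:
    def test_backbone_stage_shapes_at_608(self, full_model):
        with nn.no_grad():
            p3, p4, p5 = full_model.backbone(
                nn.Tensor(np.zeros((1, 3, 608, 608), dtype=np.float32)))
        assert p3.shape == (1, 256, 76, 76)
        assert p4.shape == (1, 512, 38, 38)
        assert p5.shape == (1, 1024, 19, 19)

    def test_three_head_grids_at_608(self, full_model):
        outs = full_model(np.zeros((1, 3, 608, 608), dtype=np.float32))
        assert [o.shape for o in outs] == [
            (1, 18, 76, 76), (1, 18, 38, 38), (1, 18, 19, 19)]

    def test_simam_adds_no_parameters_at_full_width(self, full_model):
        without = build_model(ArchitectureSpec(attention=False), seed=0)
        assert full_model.num_parameters() == without.num_parameters()
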