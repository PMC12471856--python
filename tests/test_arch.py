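"""HIRD-Net construction: shape ledger, block contracts, parameter count."""

import numpy as np
import pytest

import hirdnet as hn
from hirdnet.arch import (PRINTED_SHAPES, DenseBlock, HIRDNetConfig,
                          InceptionBlock, ResidualBlock, SECABlock)
from hirdnet.nn.layers import Conv2d
from hirdnet.nn.tensor import Tensor, global_avg_pool

TINY = HIRDNetConfig(input_size=48, width_multiplier=0.25, seed=0)


class TestFullSizeContract:
    def test_shape_ledger_descriptor_and_parameters(self, full_model_summary):
        for name, want in PRINTED_SHAPES.items():
            assert full_model_summary["ledger"][name] == want, name
        assert full_model_summary["descriptor_width"] == 1504
        millions = full_model_summary["parameters"] / 1e6
        assert abs(millions - 4.8) <= 0.2
        # softmax head: each row is a probability vector over 5 grades
        probs = full_model_summary["probs"]
        assert probs.shape == (2, 5)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)


class TestSECA:
    def test_forced_zero_logits_halve_the_input(self):
        rng = np.random.default_rng(0)
        block = SECABlock(8, 2, rng)
        block.fc1.weight.data[:] = 0
        block.fc1.bias.data[:] = 0
        block.fc2.weight.data[:] = 0
        block.fc2.bias.data[:] = 0
        x = Tensor(rng.normal(0, 1, (2, 8, 4, 4)).astype(np.float32))
        out = block(x)
        assert np.allclose(out.data, x.data / 2.0, atol=1e-6)

    def test_attention_attenuates(self):
        rng = np.random.default_rng(1)
        block = SECABlock(16, 8, rng)
        x = rng.normal(0, 3, (2, 16, 5, 5)).astype(np.float32)
        out = block(Tensor(x)).data
        assert np.all(np.abs(out) <= np.abs(x) + 1e-6)

    def test_constant_channel_descriptor(self):
        x = np.zeros((1, 3, 4, 4), dtype=np.float32)
        x[0, 1] = 2.5
        z = global_avg_pool(Tensor(x)).data
        assert z[0, 1] == pytest.approx(2.5)

    def test_indivisible_reduction_raises(self):
        with pytest.raises(ValueError, match="divide"):
            SECABlock(10, 4, np.random.default_rng(0))


class TestInception:
    def test_output_width_and_spatial_preservation(self):
        rng = np.random.default_rng(0)
        block = InceptionBlock(32, TINY, rng)
        x = Tensor(rng.normal(0, 1, (1, 32, 7, 7)).astype(np.float32))
        out = block(x, train=False)
        assert out.shape == (1, 120, 7, 7)  # 480 × width 0.25
        assert block.out_channels == 120

    def test_zero_input_gives_zero_output(self):
        block = InceptionBlock(8, TINY, np.random.default_rng(1))
        out = block(Tensor(np.zeros((1, 8, 6, 6), dtype=np.float32)), train=False)
        assert np.allclose(out.data, 0.0, atol=1e-6)

    def test_leading_channels_depend_only_on_first_branch(self):
        rng = np.random.default_rng(2)
        block = InceptionBlock(8, TINY, rng)
        x = Tensor(rng.normal(0, 1, (1, 8, 6, 6)).astype(np.float32))
        base = block(x, train=False).data.copy()
        w1 = block.b1.conv.weight.data.copy()
        block.b2b.conv.weight.data[:] *= 2.0  # perturb branch 2
        shifted = block(x, train=False).data
        n1 = TINY.scaled(128)
        assert np.allclose(shifted[:, :n1], base[:, :n1])
        assert not np.allclose(shifted[:, n1 : n1 + TINY.scaled(192)],
                               base[:, n1 : n1 + TINY.scaled(192)])
        block.b1.conv.weight.data[:] = w1 * 2.0  # perturb branch 1
        shifted2 = block(x, train=False).data
        assert not np.allclose(shifted2[:, :n1], shifted[:, :n1])


class TestResidual:
    def test_width_restored_to_256_scaled(self):
        rng = np.random.default_rng(0)
        block = ResidualBlock(120, TINY, rng)
        x = Tensor(rng.normal(0, 1, (1, 120, 7, 7)).astype(np.float32))
        assert block(x, train=False).shape == (1, 64, 7, 7)  # 256 × 0.25

    def test_zero_branch_reduces_to_shortcut(self):
        rng = np.random.default_rng(1)
        unit = ResidualBlock(16, TINY, rng).units[1]  # identity-shortcut unit
        unit.expand.conv.weight.data[:] = 0  # zero the final 1×1
        x = Tensor(rng.normal(0, 1, (1, 64, 5, 5)).astype(np.float32))
        out = unit(x, train=False)
        assert np.allclose(out.data, x.data, atol=1e-6)

    def test_shortcut_carries_gradient_past_zero_branch(self):
        rng = np.random.default_rng(2)
        unit = ResidualBlock(16, TINY, rng).units[1]
        unit.expand.conv.weight.data[:] = 0
        x = Tensor(rng.normal(0, 1, (1, 64, 5, 5)).astype(np.float32), requires_grad=True)
        unit(x, train=False).sum().backward()
        assert np.abs(x.grad).max() > 0


class TestDense:
    def test_growth_and_input_passthrough(self):
        rng = np.random.default_rng(0)
        block = DenseBlock(120, TINY, rng)
        x = rng.normal(0, 1, (1, 120, 3, 3)).astype(np.float32)
        out = block(Tensor(x), train=False)
        assert out.shape == (1, 120 + 6 * 16, 3, 3)  # growth 64 × 0.25
        assert block.out_channels == 216
        # dense concatenation preserves the input verbatim in the leading slots
        assert np.array_equal(out.data[:, :120], x)

    def test_zero_input_zero_output(self):
        block = DenseBlock(16, TINY, np.random.default_rng(1))
        out = block(Tensor(np.zeros((1, 16, 3, 3), dtype=np.float32)), train=False)
        assert np.allclose(out.data, 0.0, atol=1e-6)


class TestParameterCounting:
    def test_conv_counting_examples(self):
        rng = np.random.default_rng(0)
        conv = Conv2d(3, 4, 1, bias=True, rng=rng)
        assert conv.weight.data.size + conv.bias.data.size == 16  # 3·4 + 4
        conv2 = Conv2d(64, 64, 3, bias=False, rng=rng)
        assert conv2.weight.data.size == 36864


class TestTinyTopology:
    def test_quarter_width_has_identical_topology(self, tiny_model):
        from conftest import SMOKE_INPUT

        ledger = tiny_model.shape_ledger()
        assert set(ledger) == set(PRINTED_SHAPES)
        # channel plan scales by exactly 1/4, spatial plan by the input ratio
        for name, (h, w, c) in PRINTED_SHAPES.items():
            th, tw, tc = ledger[name]
            assert tc * 4 == c, name
            assert th == max(1, h * SMOKE_INPUT // 224), name
        assert tiny_model.descriptor_width == 1504 // 4

    def test_gradients_finite_for_every_parameter(self, tiny_model):
        from conftest import SMOKE_INPUT
        from hirdnet.objectives import focal_loss_graph

        rng = np.random.default_rng(0)
        x = rng.random((2, 3, SMOKE_INPUT, SMOKE_INPUT), dtype=np.float32)
        onehot = np.eye(5, dtype=np.float32)[[0, 3]]
        probs = tiny_model(x, train=True)
        loss = focal_loss_graph(probs, onehot)
        loss.backward()
        params = tiny_model.parameters()
        assert len(params) > 100
        for p in params:
            assert p.grad is not None
            assert np.all(np.isfinite(p.grad))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="multiple of 16"):
            HIRDNetConfig(input_size=100)
        with pytest.raises(ValueError, match="dropout"):
            HIRDNetConfig(dropout_rate=1.0)
        with pytest.raises(ValueError, match="seca_reduction"):
            HIRDNetConfig(width_multiplier=0.1)
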