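"""Equation-level tests of the network building blocks against
independent brute-force implementations."""

import numpy as np
import pytest

from dfenet.nn import Tensor
from dfenet.blocks import (
    ChannelSE,
    ConcurrentSE,
    ConvBlock,
    DenseBlock,
    PredictionBlock,
    SpatialSE,
    TransitionBlock,
    se_bottleneck_width,
)


def brute_force_cse(x, fc1_w, fc1_b, fc2_w, fc2_b):
    """Straight-line channel SE: squeeze (mean), excite (FC-ReLU-FC-sigmoid),
    rescale.  Loops only, no vectorized shortcuts."""
    n, c, w = x.shape
    out = np.zeros_like(x)
    for b in range(n):
        z = np.array([sum(x[b, k, i] for i in range(w)) / w for k in range(c)])
        hidden = []
        for j in range(fc1_w.shape[1]):
            acc = fc1_b[j]
            for k in range(c):
                acc += z[k] * fc1_w[k, j]
            hidden.append(max(acc, 0.0))
        for k in range(c):
            acc = fc2_b[k]
            for j in range(len(hidden)):
                acc += hidden[j] * fc2_w[j, k]
            s = 1.0 / (1.0 + np.exp(-acc))
            for i in range(w):
                out[b, k, i] = s * x[b, k, i]
    return out


def brute_force_sse(x, conv_w, conv_b):
    """Straight-line spatial SE: kernel-1 channel squeeze, sigmoid, rescale."""
    n, c, w = x.shape
    out = np.zeros_like(x)
    for b in range(n):
        for q in range(w):
            logit = conv_b[0]
            for k in range(c):
                logit += conv_w[0, k, 0] * x[b, k, q]
            gate = 1.0 / (1.0 + np.exp(-logit))
            for k in range(c):
                out[b, k, q] = gate * x[b, k, q]
    return out


class TestChannelSE:
    def test_matches_brute_force_on_random_inputs(self, rng):
        for trial in range(20):
            c = int(rng.integers(2, 12))
            w = int(rng.integers(3, 15))
            block = ChannelSE(c, 4, rng)
            x = rng.normal(0, 2, (2, c, w))
            got = block(Tensor(x)).data
            want = brute_force_cse(
                x, block.fc1.weight.data, block.fc1.bias.data,
                block.fc2.weight.data, block.fc2.bias.data)
            np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-9)

    def test_squeeze_is_channel_mean(self, rng):
        x = np.zeros((1, 2, 4))
        x[0, 0] = [1, 2, 3, 4]
        block = ChannelSE(2, 1, rng)
        z = x.mean(axis=2)
        assert z[0, 0] == pytest.approx(2.5)
        assert z[0, 1] == pytest.approx(0.0)

    def test_gates_strictly_in_unit_interval(self, rng):
        # moderate inputs: in exact arithmetic sigmoid never reaches 0 or 1,
        # but float64 saturates once |logit| exceeds ~37
        block = ChannelSE(8, 2, rng)
        x = rng.normal(0, 5, (4, 8, 30))
        g = block.gates(Tensor(x)).data
        assert np.all(g > 0) and np.all(g < 1)

    def test_gates_bounded_even_for_extreme_inputs(self, rng):
        block = ChannelSE(8, 2, rng)
        x = rng.normal(0, 1000, (2, 8, 30))
        g = block.gates(Tensor(x)).data
        assert np.all(g >= 0) and np.all(g <= 1)

    def test_saturated_gates_approach_identity(self, rng):
        block = ChannelSE(4, 2, rng)
        block.fc2.bias.data[:] = 50.0  # sigmoid(~50) == 1 to double precision
        block.fc2.weight.data[:] = 0.0
        x = rng.normal(size=(2, 4, 10))
        np.testing.assert_allclose(block(Tensor(x)).data, x, atol=1e-6)

    def test_shape_preserved(self, rng):
        block = ChannelSE(5, 8, rng)
        x = rng.normal(size=(3, 5, 17))
        assert block(Tensor(x)).shape == x.shape

    def test_bottleneck_width_rounds_with_floor_one(self):
        assert se_bottleneck_width(24, 8) == 3
        assert se_bottleneck_width(43, 8) == 5   # round(5.375)
        assert se_bottleneck_width(3, 8) == 1    # floor of one


class TestSpatialSE:
    def test_matches_brute_force_on_random_inputs(self, rng):
        for trial in range(20):
            c = int(rng.integers(2, 10))
            w = int(rng.integers(3, 12))
            block = SpatialSE(c, rng)
            x = rng.normal(0, 2, (2, c, w))
            got = block(Tensor(x)).data
            want = brute_force_sse(x, block.conv.weight.data, block.conv.bias.data)
            np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-9)

    def test_zero_weights_halve_the_input(self, rng):
        block = SpatialSE(3, rng)
        block.conv.weight.data[:] = 0.0
        block.conv.bias.data[:] = 0.0
        x = rng.normal(size=(2, 3, 8))
        np.testing.assert_allclose(block(Tensor(x)).data, 0.5 * x)

    def test_suppressed_position_zeroes_all_channels(self, rng):
        block = SpatialSE(3, rng)
        x = rng.normal(size=(1, 3, 8))
        gates = block.gates(Tensor(x)).data[0, 0]
        out = block(Tensor(x)).data
        q = int(np.argmin(gates))
        np.testing.assert_allclose(out[0, :, q], gates[q] * x[0, :, q])


class TestConcurrentSE:
    def test_idempotent_when_branches_agree(self, rng):
        block = ConcurrentSE(4, 2, rng, combine="max")
        x = rng.normal(size=(2, 4, 6))
        a = block.cse(Tensor(x)).data
        b = block.sse(Tensor(x)).data
        combined = block(Tensor(x)).data
        np.testing.assert_allclose(combined, np.maximum(a, b))

    def test_zero_input_gives_zero_output(self, rng):
        block = ConcurrentSE(4, 2, rng)
        out = block(Tensor(np.zeros((1, 4, 6)))).data
        np.testing.assert_array_equal(out, 0.0)

    def test_max_combination_dominates_both_branches(self, rng):
        block = ConcurrentSE(4, 2, rng, combine="max")
        x = np.abs(rng.normal(size=(2, 4, 6)))
        a = block.cse(Tensor(x)).data
        b = block.sse(Tensor(x)).data
        combined = block(Tensor(x)).data
        assert np.all(combined >= a - 1e-12)
        assert np.all(combined >= b - 1e-12)

    def test_sum_combination(self, rng):
        block = ConcurrentSE(4, 2, rng, combine="sum")
        x = rng.normal(size=(1, 4, 5))
        np.testing.assert_allclose(
            block(Tensor(x)).data,
            block.cse(Tensor(x)).data + block.sse(Tensor(x)).data)


class TestStructuralBlocks:
    def test_conv_block_shape_contract(self, rng):
        blk = ConvBlock(24, 12, rng)
        blk.eval()
        out = blk(Tensor(rng.normal(size=(2, 24, 250))))
        assert out.shape == (2, 12, 250)

    def test_conv_block_deterministic_in_eval(self, rng):
        blk = ConvBlock(4, 3, rng)
        blk.eval()
        x = rng.normal(size=(1, 4, 30))
        np.testing.assert_array_equal(blk(Tensor(x)).data, blk(Tensor(x)).data)

    def test_dense_block_channel_arithmetic(self, rng):
        blk = DenseBlock(24, 12, 4, rng)
        assert blk.out_channels == 72
        # each layer consumes the cumulative concatenation
        assert [l.conv.in_channels for l in blk.layers] == [24, 36, 48, 60]
        blk.eval()
        out = blk(Tensor(rng.normal(size=(1, 24, 50))))
        assert out.shape == (1, 72, 50)

    def test_dense_block_zero_layers_is_identity(self, rng):
        blk = DenseBlock(5, 12, 0, rng)
        x = rng.normal(size=(1, 5, 10))
        np.testing.assert_array_equal(blk(Tensor(x)).data, x)

    def test_dense_block_output_embeds_input(self, rng):
        blk = DenseBlock(3, 2, 2, rng)
        blk.eval()
        x = rng.normal(size=(1, 3, 10))
        out = blk(Tensor(x)).data
        np.testing.assert_array_equal(out[:, :3], x)

    def test_transition_block_compression_arithmetic(self, rng):
        blk = TransitionBlock(72, 0.6, rng)
        assert blk.out_channels == 43  # floor(0.6 * 72)
        blk.eval()
        out = blk(Tensor(rng.normal(size=(1, 72, 250))))
        assert out.shape == (1, 43, 125)

    def test_transition_no_compression_keeps_channels(self, rng):
        blk = TransitionBlock(10, 1.0, rng)
        assert blk.out_channels == 10

    def test_prediction_head_bias_passthrough(self, rng):
        head = PredictionBlock(6, 3, rng, output_scale=1.0)
        head.fc.weight.data[:] = 0.0
        head.fc.bias.data[:] = [50.0, 120.0, 200.0]
        out = head(Tensor(rng.normal(size=(2, 6, 30)))).data
        np.testing.assert_allclose(out, [[50, 120, 200], [50, 120, 200]])

    def test_prediction_head_relu_clamps_negative(self, rng):
        head = PredictionBlock(4, 3, rng)
        head.fc.weight.data[:] = 0.0
        head.fc.bias.data[:] = -1.0
        out = head(Tensor(rng.normal(size=(1, 4, 10)))).data
        np.testing.assert_array_equal(out, 0.0)

    def test_prediction_head_always_three_outputs(self, rng):
        head = PredictionBlock(7, 3, rng)
        for w in (5, 62, 250):
            out = head(Tensor(rng.normal(size=(2, 7, w))))
            assert out.shape == (2, 3)
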