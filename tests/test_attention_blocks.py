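import numpy as np
import pytest

from nodseg.attention_blocks import (CBAM3d, DilatedECA3d, SEBlock3d,
                                     SpatialAttention3d, build_attention,
                                     channel_pool_stats, dynamic_kernel_size)
from nodseg.nn import Identity, no_grad

import oracles


def _as_np(t):
    return t.numpy() if hasattr(t, "numpy") else np.asarray(t)


class TestChannelPoolStats:
    def test_constant_field(self):
        x = np.full((3, 2, 4, 4), 2.5, dtype=np.float32)
        avg, mx = channel_pool_stats(x)
        assert np.allclose(_as_np(avg), 2.5) and np.allclose(_as_np(mx), 2.5)
        assert _as_np(avg).shape == (1, 2, 4, 4)

    def test_hand_values(self):
        x = np.zeros((2, 1, 1, 1), dtype=np.float32)
        x[0, 0, 0, 0], x[1, 0, 0, 0] = 1.0, 3.0
        avg, mx = channel_pool_stats(x)
        assert _as_np(avg)[0, 0, 0, 0] == pytest.approx(2.0)
        assert _as_np(mx)[0, 0, 0, 0] == pytest.approx(3.0)

    def test_single_channel_identity(self, rng):
        x = rng.normal(size=(1, 2, 3, 3)).astype(np.float32)
        avg, mx = channel_pool_stats(x)
        assert np.allclose(_as_np(avg), x) and np.allclose(_as_np(mx), x)

    def test_empty_channel_axis_rejected(self):
        with pytest.raises(ValueError):
            channel_pool_stats(np.zeros((0, 2, 2, 2), dtype=np.float32))


class TestDynamicKernelSize:
    @pytest.mark.parametrize("C,expected", [
        (512, 5),   # t = 9/2 + 1/2 = 5
        (256, 5),   # t = 4.5, nearest odd 5
        (4, 1),     # t = 1.5, nearest odd 1
        (128, 5),   # t = 4 is equidistant from 3 and 5; ties round up
        (64, 3),    # t = 3.5
        (2, 1),     # t = 1, floor at 1
    ])
    def test_examples(self, C, expected):
        assert dynamic_kernel_size(C) == expected

    def test_invalid_channels(self):
        with pytest.raises(ValueError):
            dynamic_kernel_size(0)


class TestSpatialAttention:
    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            SpatialAttention3d(kernel=4)

    def test_zero_conv_gives_half_gate(self, rng):
        block = SpatialAttention3d(kernel=3, rng=rng)
        block.conv.weight.data[:] = 0.0
        block.conv.bias.data[:] = 0.0
        x = rng.normal(size=(3, 2, 4, 4)).astype(np.float32)
        out = _as_np(block(x))
        assert np.allclose(out, 0.5 * x, atol=1e-6)

    def test_gate_bounds_and_contraction(self, rng):
        block = SpatialAttention3d(kernel=7, rng=rng)
        x = np.abs(rng.normal(size=(4, 3, 5, 5))).astype(np.float32)
        m = _as_np(block.attention_map(x))
        assert np.all(m > 0) and np.all(m < 1)
        out = _as_np(block(x))
        assert np.all(np.abs(out) <= np.abs(x) + 1e-7)

    def test_matches_loop_oracle(self, rng):
        block = SpatialAttention3d(kernel=7, rng=rng)
        x = rng.normal(size=(4, 3, 5, 5)).astype(np.float32)
        with no_grad():
            got = _as_np(block(x))
        want = oracles.spatial_attention_loops(x, block)
        assert np.abs(got - want).max() < 1e-5

    def test_shape_preserved_and_deterministic(self, rng):
        block = SpatialAttention3d(rng=rng)
        x = rng.normal(size=(6, 2, 8, 8)).astype(np.float32)
        with no_grad():
            a, b = _as_np(block(x)), _as_np(block(x))
        assert a.shape == x.shape
        assert np.array_equal(a, b)


class TestDilatedECA:
    def test_channels_not_divisible_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            DilatedECA3d(channels=6)

    def test_group_order_and_shape(self, rng):
        block = DilatedECA3d(8, rng=rng)
        assert block.group_channels == 2
        x = rng.normal(size=(8, 4, 8, 8)).astype(np.float32)
        with no_grad():
            out = _as_np(block(x))
        assert out.shape == x.shape

    def test_zero_input_gives_zero_output_half_gate(self, rng):
        block = DilatedECA3d(8, rng=rng)
        # zero biases so the multiscale conv of zero stays exactly zero
        for i in range(4):
            getattr(block, f"depthwise{i}").bias.data[:] = 0.0
            getattr(block, f"pointwise{i}").bias.data[:] = 0.0
        block.conv1d.bias.data[:] = 0.0
        x = np.zeros((8, 2, 4, 4), dtype=np.float32)
        with no_grad():
            gate = _as_np(block.gate(block.multiscale_conv(x)))
            out = _as_np(block(x))
        assert np.allclose(gate, 0.5)
        assert np.allclose(out, 0.0)

    def test_zero_conv1d_forces_half_gate(self, rng):
        block = DilatedECA3d(8, rng=rng)
        block.conv1d.weight.data[:] = 0.0
        block.conv1d.bias.data[:] = 0.0
        x = rng.normal(size=(8, 2, 4, 4)).astype(np.float32)
        with no_grad():
            gate = _as_np(block.gate(block.multiscale_conv(x)))
        assert np.allclose(gate, 0.5)

    def test_gate_in_half_open_interval(self, rng):
        block = DilatedECA3d(8, rng=rng)
        x = rng.normal(size=(8, 2, 6, 6)).astype(np.float32)
        with no_grad():
            gate = _as_np(block.gate(block.multiscale_conv(x)))
        assert np.all(gate >= 0.5) and np.all(gate < 1.0)

    def test_gate_ratio_constant_per_channel(self, rng):
        block = DilatedECA3d(8, rng=rng)
        x = rng.normal(size=(8, 2, 6, 6)).astype(np.float32)
        with no_grad():
            xc = _as_np(block.multiscale_conv(x))
            out = _as_np(block(x))
        ratio = out / np.where(np.abs(xc) < 1e-6, np.nan, xc)
        for c in range(8):
            vals = ratio[c][np.isfinite(ratio[c])]
            assert vals.size > 0
            assert np.nanmax(vals) - np.nanmin(vals) < 1e-4
            assert 0.5 - 1e-6 <= vals[0] < 1.0

    def test_matches_loop_oracle(self, rng):
        block = DilatedECA3d(8, rng=rng)
        x = rng.normal(size=(8, 2, 6, 6)).astype(np.float32)
        with no_grad():
            got = _as_np(block(x))
            got_gate = _as_np(block.gate(block.multiscale_conv(x)))
        want, want_gate = oracles.dilated_eca_loops(x, block)
        assert np.abs(got_gate - want_gate).max() < 1e-6
        assert np.abs(got - want).max() < 1e-5

    def test_identity_kernels_preserve_input(self):
        block = DilatedECA3d(8)
        k = block.kernel_size
        mid = k // 2
        for i in range(4):
            dw_l = getattr(block, f"depthwise{i}")
            dw_l.weight.data[:] = 0.0
            dw_l.weight.data[:, 0, mid, mid, mid] = 1.0
            dw_l.bias.data[:] = 0.0
            pw = getattr(block, f"pointwise{i}")
            pw.weight.data[:] = np.eye(2, dtype=np.float32).reshape(2, 2, 1, 1, 1)
            pw.bias.data[:] = 0.0
        x = np.random.default_rng(0).normal(size=(8, 3, 5, 5)).astype(np.float32)
        with no_grad():
            xc = _as_np(block.multiscale_conv(x))
        assert np.abs(xc - x).max() < 1e-6


class TestCBAM:
    def test_config_errors(self):
        with pytest.raises(ValueError):
            CBAM3d(8, kernel=4)
        with pytest.raises(ValueError):
            CBAM3d(4, reduction=16)
        with pytest.raises(ValueError):
            CBAM3d(8, reduction=4, gate_mode="bogus")

    def test_zero_mlp_gives_half_gate(self, rng):
        block = CBAM3d(6, reduction=2, rng=rng)
        for fc in (block.fc1, block.fc2):
            fc.weight.data[:] = 0.0
            fc.bias.data[:] = 0.0
        x = rng.normal(size=(6, 2, 4, 4)).astype(np.float32)
        with no_grad():
            gate = _as_np(block.channel_gate(x))
        assert np.allclose(gate, 0.5)

    def test_constant_input_doubles_logit(self, rng):
        block = CBAM3d(6, reduction=2, rng=rng)
        x = np.full((6, 2, 4, 4), 1.7, dtype=np.float32)
        with no_grad():
            gate = _as_np(block.channel_gate(x))
        desc = x.mean(axis=(1, 2, 3))
        h = np.maximum(desc @ block.fc1.weight.data + block.fc1.bias.data, 0)
        logit = h @ block.fc2.weight.data + block.fc2.bias.data
        assert np.allclose(gate, oracles.sigmoid(2 * logit), atol=1e-6)

    @pytest.mark.parametrize("mode,hi", [("summed_logits", 1.0),
                                         ("per_branch_sigmoid", 2.0)])
    def test_gate_ranges_by_mode(self, rng, mode, hi):
        block = CBAM3d(6, reduction=2, gate_mode=mode, rng=rng)
        x = rng.normal(size=(6, 3, 4, 4)).astype(np.float32)
        with no_grad():
            gate = _as_np(block.channel_gate(x))
        assert np.all(gate > 0) and np.all(gate < hi)

    @pytest.mark.parametrize("mode", ["summed_logits", "per_branch_sigmoid"])
    def test_matches_loop_oracle(self, rng, mode):
        block = CBAM3d(6, reduction=2, gate_mode=mode, rng=rng)
        x = rng.normal(size=(6, 2, 4, 4)).astype(np.float32)
        with no_grad():
            got = _as_np(block(x))
        want = oracles.cbam_loops(x, block)
        assert np.abs(got - want).max() < 1e-5

    def test_zero_input_zero_output(self, rng):
        block = CBAM3d(6, reduction=2, rng=rng)
        with no_grad():
            out = _as_np(block(np.zeros((6, 2, 4, 4), dtype=np.float32)))
        assert np.allclose(out, 0.0)


class TestSEBlock:
    def test_zero_fc_halves_input(self, rng):
        block = SEBlock3d(8, reduction=4, rng=rng)
        for fc in (block.fc1, block.fc2):
            fc.weight.data[:] = 0.0
            fc.bias.data[:] = 0.0
        x = rng.normal(size=(8, 2, 4, 4)).astype(np.float32)
        with no_grad():
            out = _as_np(block(x))
        assert np.allclose(out, 0.5 * x, atol=1e-6)

    def test_weights_bounded_under_scaling(self, rng):
        block = SEBlock3d(8, reduction=4, rng=rng)
        x = np.abs(rng.normal(size=(8, 2, 4, 4))).astype(np.float32)
        # moderate scales: in float32 a saturated sigmoid rounds to exactly
        # 1.0 once the logit passes ~17, which is a representation artifact,
        # not a violation of the open-interval property
        for scale in (0.5, 1.0, 4.0):
            with no_grad():
                s = _as_np(block.weights(scale * x))
            assert np.all(s > 0) and np.all(s < 1)

    def test_matches_loop_oracle(self, rng):
        block = SEBlock3d(8, reduction=4, rng=rng)
        x = rng.normal(size=(8, 2, 4, 4)).astype(np.float32)
        with no_grad():
            got = _as_np(block(x))
        want, _ = oracles.se_loops(x, block)
        assert np.abs(got - want).max() < 1e-6

    def test_hidden_width_floor(self):
        block = SEBlock3d(8, reduction=16)   # C < reduction: hidden max(1, C/r)
        assert block.fc1.weight.shape == (8, 1)


def test_build_attention_factory(rng):
    assert isinstance(build_attention("none", 8), Identity)
    assert isinstance(build_attention("SA", 8, rng=rng), SpatialAttention3d)
    assert isinstance(build_attention("DilatedECA", 8, rng=rng), DilatedECA3d)
    assert isinstance(build_attention("CBAM", 16, rng=rng), CBAM3d)
    assert isinstance(build_attention("SE", 16, rng=rng), SEBlock3d)
    with pytest.raises(ValueError):
        build_attention("bogus", 8)


def test_all_blocks_preserve_shape(rng):
    x = rng.normal(size=(8, 4, 8, 8)).astype(np.float32)
    blocks = [SpatialAttention3d(rng=rng), DilatedECA3d(8, rng=rng),
              CBAM3d(8, reduction=4, rng=rng), SEBlock3d(8, reduction=4, rng=rng)]
    for block in blocks:
        with no_grad():
            assert _as_np(block(x)).shape == x.shape
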