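"""Oracle checks for the dilated convolution and the MLDR/MLR blocks."""

import numpy as np
import pytest

from mildnet import (
    ConfigurationError,
    DilatedConvSpec,
    dilated_convolve,
    effective_receptive_field,
    mldr_block,
    mldr_forward,
    mlr_block,
    mlr_forward,
)
from mildnet import nn
from mildnet.nn.autograd import Tensor


def conv_oracle(x, w, d):
    """Direct nested-loop dilated cross-correlation with zero padding."""
    b, c, h, ww = x.shape
    o, _, k, _ = w.shape
    p = d * (k - 1) // 2
    out = np.zeros((b, o, h, ww))
    for bi in range(b):
        for oi in range(o):
            for y0 in range(h):
                for x0 in range(ww):
                    acc = 0.0
                    for ci in range(c):
                        for i in range(k):
                            for j in range(k):
                                yy = y0 + i * d - p
                                xx = x0 + j * d - p
                                if 0 <= yy < h and 0 <= xx < ww:
                                    acc += x[bi, ci, yy, xx] * w[oi, ci, i, j]
                    out[bi, oi, y0, x0] = acc
    return out


class TestDilatedConvolve:
    def test_all_ones_d1_center(self):
        x = np.ones((1, 1, 5, 5))
        w = np.ones((1, 1, 3, 3))
        out = dilated_convolve(x, DilatedConvSpec(1, 1, 3, 1), w)
        assert out[0, 0, 2, 2] == 9.0
        assert out[0, 0, 0, 0] == 4.0  # corner sees a 2x2 overlap

    def test_all_ones_d2_center_and_corner(self):
        x = np.ones((1, 1, 5, 5))
        w = np.ones((1, 1, 3, 3))
        out = dilated_convolve(x, DilatedConvSpec(1, 1, 3, 2), w)
        assert out[0, 0, 2, 2] == 9.0
        assert out[0, 0, 0, 0] == 4.0
        np.testing.assert_allclose(out, conv_oracle(x, w, 2))

    def test_delta_kernel_is_identity(self, rng):
        x = rng.normal(size=(2, 1, 6, 7))
        w = np.zeros((1, 1, 3, 3))
        w[0, 0, 1, 1] = 1.0
        for d in (1, 2, 5):
            out = dilated_convolve(x, DilatedConvSpec(1, 1, 3, d), w)
            np.testing.assert_array_equal(out, x)

    @pytest.mark.parametrize("dilation", [1, 2, 3, 5])
    def test_matches_nested_loop_oracle(self, rng, dilation):
        for _ in range(10):
            x = rng.normal(size=(1, 2, 8, 8))
            w = rng.normal(size=(3, 2, 3, 3))
            out = dilated_convolve(x, DilatedConvSpec(2, 3, 3, dilation), w)
            np.testing.assert_allclose(out, conv_oracle(x, w, dilation),
                                       rtol=1e-12, atol=1e-12)

    def test_d1_equals_standard_cross_correlation(self, rng):
        from scipy.ndimage import correlate

        x = rng.normal(size=(1, 1, 8, 8))
        w = rng.normal(size=(1, 1, 3, 3))
        out = dilated_convolve(x, DilatedConvSpec(1, 1, 3, 1), w)
        ref = correlate(x[0, 0], w[0, 0], mode="constant")
        np.testing.assert_allclose(out[0, 0], ref, atol=1e-12)

    @pytest.mark.parametrize("dilation,rf", [(1, 3), (3, 7), (5, 11)])
    def test_impulse_response_support(self, dilation, rf):
        """Receptive field k + (k-1)(d-1) shows as the impulse-response support."""
        assert effective_receptive_field(3, dilation) == rf
        n = 15
        x = np.zeros((1, 1, n, n))
        x[0, 0, n // 2, n // 2] = 1.0
        out = dilated_convolve(x, DilatedConvSpec(1, 1, 3, dilation),
                               np.ones((1, 1, 3, 3)))
        ys, xs = np.nonzero(out[0, 0])
        assert ys.max() - ys.min() + 1 == rf
        assert xs.max() - xs.min() + 1 == rf

    def test_configuration_errors(self):
        with pytest.raises(ConfigurationError):
            DilatedConvSpec(1, 1, 3, 0)  # non-positive dilation
        with pytest.raises(ConfigurationError):
            DilatedConvSpec(1, 1, 4, 1)  # even kernel
        spec = DilatedConvSpec(2, 1, 3, 1)
        with pytest.raises(ConfigurationError):
            dilated_convolve(np.ones((1, 3, 4, 4)), spec, np.ones((1, 2, 3, 3)))


def _zero_all_convs(block):
    for name, p in block.named_parameters():
        if "weight" in name and p.data.ndim == 4:
            p.data[...] = 0.0


class TestMLDRBlock:
    def test_shape_contract(self, rng):
        block = mldr_block(32, 64, rng=rng)
        out = mldr_forward(rng.normal(size=(1, 32, 64, 64)), block)
        assert out.shape == (1, 64, 64, 64)

    def test_zero_weights_identity_channels(self, rng):
        """With F == 0 at both levels the block reduces to ReLU(2x)."""
        block = mldr_block(3, 3, rng=rng)
        _zero_all_convs(block)
        x = rng.normal(size=(2, 3, 8, 8))
        out = mldr_forward(x, block)
        np.testing.assert_allclose(out, np.maximum(2.0 * x, 0.0), atol=1e-12)

    def test_scalar_chain_hand_trace(self, rng):
        """Single-pixel input against an explicit scalar trace of the block."""
        block = mldr_block(1, 1, rng=rng)
        # freeze BN stats to non-trivial values
        v = 1.7
        stats = []
        for mod in block.modules():
            if isinstance(mod, nn.BatchNorm2d):
                mod.running_mean[...] = 0.3
                mod.running_var[...] = 2.0
                mod.gamma.data[...] = 1.2
                mod.beta.data[...] = 0.1
                stats.append(mod)
        assert len(stats) == 2  # one BN per level

        def bn(x):
            return 1.2 * (x - 0.3) / np.sqrt(2.0 + 1e-5) + 0.1

        def level(x, level_mod):
            a = max(bn(x), 0.0)
            f = sum(float(conv.weight.data[0, 0, 1, 1]) * a
                    for conv in level_mod.branches)  # 1x1 spatial: center tap only
            return max(f + x, 0.0)

        y = level(v, block.levels[0])
        y = level(y, block.levels[1])
        expected = max(y + v, 0.0)
        out = mldr_forward(np.full((1, 1, 1, 1), v), block)
        np.testing.assert_allclose(out[0, 0, 0, 0], expected, rtol=1e-10)

    def test_channel_mismatch_raises(self, rng):
        block = mldr_block(4, 8, rng=rng)
        with pytest.raises(ConfigurationError):
            mldr_forward(np.ones((1, 3, 8, 8)), block)

    def test_translation_equivariance_away_from_borders(self, rng):
        block = mldr_block(1, 1, rng=rng)
        block.eval()
        x = rng.normal(size=(1, 1, 24, 24))
        xs = np.zeros_like(x)
        xs[:, :, 1:, :] = x[:, :, :-1, :]  # shift down by 1 px
        out = mldr_forward(x, block)
        outs = mldr_forward(xs, block)
        m = 12  # beyond the block's receptive-field halfwidth
        np.testing.assert_allclose(outs[:, :, m + 1 : -m, m : -m],
                                   out[:, :, m : -m - 1, m : -m], atol=1e-9)

    def test_gradient_reaches_input(self, rng):
        for block in (mldr_block(2, 4, rng=rng), mlr_block(3, rng=rng)):
            block.train()
            x = Tensor(rng.normal(size=(2, block.spec.in_channels, 8, 8)),
                       requires_grad=True)
            nn.mean(block(x)).backward()
            assert x.grad is not None and np.abs(x.grad).max() > 0

    def test_concat_fusion_mode(self, rng):
        block = mldr_block(2, 4, fusion="concat", rng=rng)
        out = mldr_forward(rng.normal(size=(1, 2, 8, 8)), block)
        assert out.shape == (1, 4, 8, 8)


class TestMLRBlock:
    def test_preserves_shape(self, rng):
        block = mlr_block(64, rng=rng)
        out = mlr_forward(rng.normal(size=(1, 64, 32, 32)), block)
        assert out.shape == (1, 64, 32, 32)

    def test_zero_weights_gives_relu_2x(self, rng):
        block = mlr_block(2, rng=rng)
        _zero_all_convs(block)
        x = rng.normal(size=(1, 2, 6, 6))
        out = mlr_forward(x, block)
        np.testing.assert_allclose(out, np.maximum(2.0 * x, 0.0), atol=1e-12)

    def test_matches_straight_line_reimplementation(self, rng):
        """Fixed weights vs an independent flat re-implementation on 4x4."""
        block = mlr_block(1, rng=rng)
        x = rng.normal(size=(1, 1, 4, 4))

        def bn_eval(arr, mod):
            return (mod.gamma.data[0] * (arr - mod.running_mean[0])
                    / np.sqrt(mod.running_var[0] + mod.eps) + mod.beta.data[0])

        def level_oracle(arr, level_mod):
            a = np.maximum(bn_eval(arr, level_mod.bn), 0.0)
            for conv in level_mod.branches:
                a = conv_oracle(a, conv.weight.data, 1)
            return np.maximum(a + arr, 0.0)

        y = level_oracle(x, block.levels[0])
        y = level_oracle(y, block.levels[1])
        expected = np.maximum(y + x, 0.0)
        np.testing.assert_allclose(mlr_forward(x, block), expected, atol=1e-10)

    def test_channel_change_rejected(self, rng):
        from mildnet import ResidualBlockSpec

        with pytest.raises(ConfigurationError):
            ResidualBlockSpec("MLR", 4, 8)

    def test_residual_addition_count(self, rng):
        """N levels -> N inner additions plus one outer (residual-of-residual)."""
        for n in (1, 2, 3):
            block = mldr_block(2, 2, levels=n, rng=rng)
            assert len(block.levels) == n
            assert block.outer_shortcut is None  # identity outer shortcut
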