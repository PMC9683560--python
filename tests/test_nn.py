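"""Autodiff backend: shapes, gradient correctness, layer semantics."""

import numpy as np
import pytest

import fundusmt.nn as nn
from fundusmt.losses import dice_loss, dr_ce, seg_ce
from fundusmt.nn import Parameter, Tensor


def fd_gradient(make_loss, x0, eps=1e-5):
    """Central finite-difference gradient of a scalar-valued function."""
    num = np.zeros_like(x0)
    it = np.nditer(x0, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp, xm = x0.copy(), x0.copy()
        xp[i] += eps
        xm[i] -= eps
        num[i] = (float(make_loss(Tensor(xp))) - float(make_loss(Tensor(xm)))) / (2 * eps)
    return num


def analytic_gradient(make_loss, x0):
    x = Parameter(x0)
    x.data = x0.astype(np.float64)
    make_loss(x).backward()
    return x.grad


rng = np.random.default_rng(42)
_W = rng.normal(size=(2, 3, 3, 3))
_TARGET = (np.arange(2 * 2 * 3 * 3).reshape(2, 2, 3, 3) % 2).astype(float)


class TestConv2d:
    @pytest.mark.parametrize("stride,dilation,expect_hw", [
        (1, 1, (6, 6)), (2, 1, (3, 3)), (1, 2, (6, 6))])
    def test_output_shapes(self, stride, dilation, expect_hw):
        x = Tensor(rng.normal(size=(1, 3, 6, 6)))
        w = Tensor(_W)
        y = nn.conv2d(x, w, stride=stride, padding=dilation, dilation=dilation)
        assert y.data.shape == (1, 2, *expect_hw)

    def test_matches_direct_convolution(self):
        # independent oracle: explicit loop over output positions
        x0 = rng.normal(size=(1, 2, 5, 5))
        w0 = rng.normal(size=(3, 2, 3, 3))
        y = nn.conv2d(Tensor(x0), Tensor(w0), padding=1).data
        xp = np.pad(x0, ((0, 0), (0, 0), (1, 1), (1, 1)))
        for co in range(3):
            for i in range(5):
                for j in range(5):
                    ref = np.sum(xp[0, :, i:i + 3, j:j + 3] * w0[co])
                    assert y[0, co, i, j] == pytest.approx(ref, rel=1e-9)

    @pytest.mark.parametrize("stride,dilation", [(1, 1), (2, 1), (1, 2)])
    def test_gradients_match_finite_differences(self, stride, dilation):
        x0 = rng.normal(size=(2, 3, 6, 6))
        pad = dilation
        tgt = _TARGET if stride == 2 else (
            np.arange(2 * 2 * 6 * 6).reshape(2, 2, 6, 6) % 2).astype(float)

        def loss(x):
            y = nn.conv2d(x, Tensor(_W), stride=stride, padding=pad,
                          dilation=dilation)
            return seg_ce(nn.sigmoid(y), tgt)

        assert np.abs(analytic_gradient(loss, x0) - fd_gradient(loss, x0)).max() < 1e-6

    def test_weight_and_bias_gradients(self):
        x0 = rng.normal(size=(1, 2, 4, 4))
        w = Parameter(rng.normal(size=(2, 2, 3, 3)))
        w.data = w.data.astype(np.float64)
        b = Parameter(np.zeros(2))
        b.data = b.data.astype(np.float64)
        tgt = (np.arange(32).reshape(1, 2, 4, 4) % 2).astype(float)
        loss = seg_ce(nn.sigmoid(nn.conv2d(Tensor(x0), w, b, padding=1)), tgt)
        loss.backward()
        for p in (w, b):
            p0 = p.data.copy()

            def loss_at(q, pp=p):
                old = pp.data
                pp.data = q
                v = float(seg_ce(nn.sigmoid(
                    nn.conv2d(Tensor(x0), w, b, padding=1)), tgt))
                pp.data = old
                return v

            num = np.zeros_like(p0)
            it = np.nditer(p0, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                qp, qm = p0.copy(), p0.copy()
                qp[i] += 1e-6
                qm[i] -= 1e-6
                num[i] = (loss_at(qp) - loss_at(qm)) / 2e-6
            assert np.abs(p.grad - num).max() < 1e-4


class TestOtherOps:
    def test_batchnorm_gradient(self):
        g = Parameter(np.array([1.3, 0.7]))
        g.data = g.data.astype(np.float64)
        b = Parameter(np.array([0.1, -0.2]))
        b.data = b.data.astype(np.float64)
        tgt = (np.arange(3 * 2 * 16).reshape(3, 2, 4, 4) % 2).astype(float)

        def loss(x):
            y = nn.batchnorm2d(x, g, b, running_mean=np.zeros(2),
                               running_var=np.ones(2), training=True)
            return seg_ce(nn.sigmoid(y), tgt)

        x0 = rng.normal(size=(3, 2, 4, 4))
        assert np.abs(analytic_gradient(loss, x0) - fd_gradient(loss, x0)).max() < 1e-6

    def test_batchnorm_normalizes_in_train_mode(self):
        g = Parameter(np.ones(3))
        b = Parameter(np.zeros(3))
        x = Tensor(rng.normal(2.0, 3.0, size=(4, 3, 8, 8)))
        y = nn.batchnorm2d(x, g, b, running_mean=np.zeros(3),
                           running_var=np.ones(3), training=True)
        assert np.abs(y.data.mean(axis=(0, 2, 3))).max() < 1e-7
        assert np.abs(y.data.std(axis=(0, 2, 3)) - 1).max() < 1e-3

    def test_upsample_preserves_constants_and_doubles_size(self):
        x = Tensor(np.full((1, 2, 5, 7), 3.25))
        y = nn.upsample_bilinear2x(x)
        assert y.data.shape == (1, 2, 10, 14)
        assert np.allclose(y.data, 3.25)

    def test_upsample_gradient(self):
        tgt = (np.arange(4 * 2 * 64).reshape(4, 2, 8, 8) % 2).astype(float)

        def loss(x):
            return dice_loss(nn.sigmoid(nn.upsample_bilinear2x(x)), tgt)

        x0 = rng.normal(size=(4, 2, 4, 4))
        assert np.abs(analytic_gradient(loss, x0) - fd_gradient(loss, x0)).max() < 1e-6

    def test_softmax_ce_gradient(self):
        def loss(x):
            return dr_ce(nn.softmax(x, axis=-1), np.array([1, 3]))

        x0 = rng.normal(size=(2, 5))
        assert np.abs(analytic_gradient(loss, x0) - fd_gradient(loss, x0)).max() < 1e-6

    def test_gap_linear_gradient(self):
        w0 = rng.normal(size=(5, 3))

        def loss(x):
            h = nn.linear(nn.global_avg_pool(x), Tensor(w0))
            return dr_ce(nn.softmax(h, axis=-1), np.array([0, 2]))

        x0 = rng.normal(size=(2, 3, 4, 4))
        assert np.abs(analytic_gradient(loss, x0) - fd_gradient(loss, x0)).max() < 1e-6

    def test_leaky_relu_slope(self):
        x = Tensor(np.array([-2.0, 3.0]))
        y = nn.leaky_relu(x, 0.1)
        np.testing.assert_allclose(y.data, [-0.2, 3.0])


class TestModules:
    def test_conv_block_shapes(self):
        r = np.random.default_rng(0)
        blk = nn.ConvBlock(r, 3, 32, stride=1)
        y = blk(Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32)))
        assert y.data.shape == (1, 32, 64, 64)
        blk2 = nn.ConvBlock(r, 32, 64, stride=2)
        assert blk2(y).data.shape == (1, 64, 32, 32)

    def test_invalid_stride_rejected(self):
        with pytest.raises(ValueError):
            nn.ConvBlock(np.random.default_rng(0), 3, 8, stride=3)

    def test_bottleneck_residual_identity_when_zeroed(self):
        r = np.random.default_rng(1)
        blk = nn.Bottleneck(r, 6)
        blk.cv2.conv.weight.data[:] = 0.0
        x = Tensor(rng.normal(size=(2, 6, 5, 5)).astype(np.float32))
        y = blk(x)
        np.testing.assert_allclose(y.data, x.data, atol=1e-6)

    def test_csp_requires_even_channels(self):
        with pytest.raises(ValueError):
            nn.BottleneckCSP(np.random.default_rng(0), 8, 7)

    def test_csp_output_shape(self):
        r = np.random.default_rng(2)
        blk = nn.BottleneckCSP(r, 6, 8, repeats=2)
        y = blk(Tensor(np.zeros((1, 6, 10, 10), dtype=np.float32)))
        assert y.data.shape == (1, 8, 10, 10)

    def test_aspp_preserves_spatial_size(self):
        r = np.random.default_rng(3)
        blk = nn.ASPP(r, 4, 6, branch=3)
        y = blk(Tensor(np.zeros((1, 4, 40, 40), dtype=np.float32)))
        assert y.data.shape == (1, 6, 40, 40)

    def test_aspp_rejects_bad_rates(self):
        with pytest.raises(ValueError):
            nn.ASPP(np.random.default_rng(0), 4, 4, branch=2, rates=(0, 6))

    def test_chained_upsample_blocks_quadruple_resolution(self):
        r = np.random.default_rng(4)
        b1 = nn.UpsampleBlock(r, 3, 4)
        b2 = nn.UpsampleBlock(r, 4, 2)
        y = b2(b1(Tensor(np.zeros((1, 3, 16, 16), dtype=np.float32))))
        assert y.data.shape == (1, 2, 64, 64)

    def test_adam_determinism(self):
        def run():
            r = np.random.default_rng(5)
            blk = nn.ConvBlock(r, 2, 4)
            opt = nn.Adam(dict(blk.named_parameters()), lr=1e-3)
            x = np.random.default_rng(6).normal(size=(2, 2, 8, 8)).astype(np.float32)
            tgt = (np.arange(2 * 4 * 64).reshape(2, 4, 8, 8) % 2).astype(float)
            for _ in range(5):
                opt.zero_grad()
                loss = seg_ce(nn.sigmoid(blk(Tensor(x))), tgt)
                loss.backward()
                opt.step()
            return {n: p.data.copy() for n, p in blk.named_parameters()}

        s1, s2 = run(), run()
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])
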