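"""Numerical checks of the autodiff engine against central differences
and against independent scipy reference implementations."""

import numpy as np
import pytest
from scipy import ndimage, signal

from boneseg import nn
from boneseg.nn import functional as F
from boneseg.nn.autodiff import Tensor, tmean


def numeric_grad(fn, arrays, wrt, eps=1e-6):
    """Central-difference gradient of scalar fn w.r.t. arrays[wrt]."""
    a = arrays[wrt]
    g = np.zeros_like(a)
    flat = a.ravel()
    gflat = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(*arrays)
        flat[i] = orig - eps
        lo = fn(*arrays)
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * eps)
    return g


def analytic_grads(op, arrays):
    tensors = [Tensor(a, requires_grad=True) for a in arrays]
    out = tmean(op(*tensors))
    out.backward()
    return [t.grad for t in tensors], out.item()


def check_op(op, arrays, atol=1e-6):
    grads, _ = analytic_grads(op, arrays)
    for i in range(len(arrays)):
        num = numeric_grad(lambda *a: _scalar(op, a), list(arrays), i)
        assert np.allclose(grads[i], num, atol=atol), f"grad mismatch for arg {i}"


def _scalar(op, arrays):
    return float(np.mean(op(*[Tensor(a) for a in arrays]).data))


RNG = np.random.default_rng(7)


def randf(*shape):
    return RNG.standard_normal(shape).astype(np.float64)


class TestGradients:
    def test_conv2d_gradcheck(self):
        x = randf(2, 3, 6, 6)
        w = randf(4, 3, 3, 3) * 0.3
        b = randf(4) * 0.1
        check_op(lambda x_, w_, b_: F.conv2d(x_, w_, b_, stride=1, pad=1), [x, w, b])

    def test_conv2d_stride2_gradcheck(self):
        x = randf(2, 2, 8, 8)
        w = randf(3, 2, 3, 3) * 0.3
        b = randf(3) * 0.1
        check_op(lambda x_, w_, b_: F.conv2d(x_, w_, b_, stride=2, pad=1), [x, w, b])

    def test_dwconv_gradcheck(self):
        x = randf(2, 4, 5, 5)
        w = randf(4, 3, 3) * 0.3
        b = randf(4) * 0.1
        check_op(F.dwconv3x3, [x, w, b])

    def test_linear_channels_gradcheck(self):
        x = randf(2, 5, 3, 3)
        w = randf(4, 5) * 0.3
        b = randf(4) * 0.1
        check_op(F.linear_channels, [x, w, b])

    def test_maxpool_gradcheck(self):
        x = randf(2, 3, 6, 6)
        check_op(F.maxpool2x2, [x])

    def test_upsample_gradcheck(self):
        x = randf(2, 2, 5, 4)
        check_op(F.upsample2x_bilinear, [x])

    @pytest.mark.parametrize("axis,mode", [(2, "max"), (3, "max"), (2, "min"), (3, "min")])
    def test_pool3_gradcheck(self, axis, mode):
        x = randf(2, 1, 5, 5)
        check_op(lambda x_: F.pool3(x_, axis, mode), [x])

    def test_group_shift_gradcheck(self):
        x = randf(2, 10, 6, 6)
        check_op(lambda x_: F.group_spatial_shift(x_, axis=2), [x])
        check_op(lambda x_: F.group_spatial_shift(x_, axis=3), [x])

    def test_batchnorm_train_gradcheck(self):
        x = randf(3, 4, 5, 5)
        gamma = 1.0 + 0.1 * randf(4)
        beta = 0.1 * randf(4)

        def op(x_, g_, b_):
            rm = np.zeros(4)
            rv = np.ones(4)
            return F.batchnorm2d(x_, g_, b_, rm, rv, training=True)

        check_op(op, [x, gamma, beta], atol=1e-5)

    def test_batchnorm_eval_gradcheck(self):
        x = randf(2, 3, 4, 4)
        gamma = 1.0 + 0.1 * randf(3)
        beta = 0.1 * randf(3)
        rm = 0.3 * randf(3)
        rv = 1.0 + 0.2 * np.abs(randf(3))
        check_op(lambda x_, g_, b_: F.batchnorm2d(x_, g_, b_, rm, rv, training=False),
                 [x, gamma, beta])

    def test_layernorm_gradcheck(self):
        x = randf(2, 6, 3, 3)
        gamma = 1.0 + 0.1 * randf(6)
        beta = 0.1 * randf(6)
        check_op(F.layernorm_channels, [x, gamma, beta], atol=1e-5)

    def test_gelu_gradcheck(self):
        x = randf(3, 4)
        check_op(F.gelu, [x])

    def test_elementwise_and_reduction_gradcheck(self):
        a = randf(3, 4)
        b = randf(3, 4)
        from boneseg.nn import autodiff as ad
        check_op(lambda x_, y_: ad.mul(ad.add(x_, y_), x_), [a, b])
        check_op(lambda x_, y_: ad.minimum(x_, y_), [a, b + 0.01])
        check_op(lambda x_, y_: ad.maximum(x_, y_), [a, b + 0.01])
        check_op(ad.relu, [a])
        check_op(ad.sigmoid, [a])

    def test_wbce_gradcheck(self):
        z = randf(2, 1, 4, 4)
        t = (RNG.random((2, 1, 4, 4)) < 0.3).astype(np.float64)
        tz = Tensor(z, requires_grad=True)
        loss = F.weighted_bce_with_logits(tz, t, pos_weight=20.0)
        loss.backward()
        num = numeric_grad(
            lambda z_: float(F.weighted_bce_with_logits(Tensor(z_), t, 20.0).data),
            [z.copy()], 0)
        assert np.allclose(tz.grad, num, atol=1e-6)


class TestForwardOracles:
    def test_conv2d_matches_scipy_correlate(self):
        x = randf(1, 2, 7, 7)
        w = randf(3, 2, 3, 3)
        b = randf(3)
        out = F.conv2d(Tensor(x), Tensor(w), Tensor(b), stride=1, pad=1).data
        for co in range(3):
            ref = b[co] + sum(
                signal.correlate2d(x[0, ci], w[co, ci], mode="same")
                for ci in range(2))
            assert np.allclose(out[0, co], ref, atol=1e-10)

    def test_maxpool_matches_ndimage(self):
        x = randf(1, 1, 8, 8)
        out = F.maxpool2x2(Tensor(x)).data[0, 0]
        ref = x[0, 0].reshape(4, 2, 4, 2).max(axis=(1, 3))
        assert np.array_equal(out, ref)

    def test_pool3_matches_grey_dilation(self):
        x = randf(1, 1, 9, 9)
        out = F.pool3(F.pool3(Tensor(x), 2, "max"), 3, "max").data[0, 0]
        ref = ndimage.grey_dilation(x[0, 0], size=(3, 3))
        assert np.allclose(out, ref)

    def test_upsample_doubles_and_interpolates(self):
        x = np.arange(16, dtype=np.float64).reshape(1, 1, 4, 4)
        out = F.upsample2x_bilinear(Tensor(x)).data[0, 0]
        assert out.shape == (8, 8)
        # interior samples follow the half-pixel bilinear rule
        assert np.isclose(out[2, 2], 0.75 * (0.75 * 5 + 0.25 * 4)
                          + 0.25 * (0.75 * 1 + 0.25 * 0))
        # global mean preserved up to border replication effects
        assert abs(out.mean() - x.mean()) < 0.5

    def test_group_shift_moves_groups(self):
        x = np.zeros((1, 5, 5, 5))
        x[0, :, 2, 2] = 1.0
        out = F.group_spatial_shift(Tensor(x), axis=2).data
        rows = [np.argmax(out[0, g, :, 2]) for g in range(5)]
        assert rows == [0, 1, 2, 3, 4]  # shifts -2..+2 applied per group


class TestOptim:
    def test_adamw_single_step_matches_hand_formula(self):
        p = Tensor(np.array([1.0, -2.0]), requires_grad=True)
        opt = nn.AdamW([p], lr=0.1, weight_decay=0.01)
        p.grad = np.array([0.5, -0.5])
        opt.step()
        # bias-corrected first step: update = g/(|g|+eps)
        expect = np.array([1.0, -2.0]) - 0.1 * (
            np.array([1.0, -1.0]) * (0.5 / (0.5 + 1e-8))
            + 0.01 * np.array([1.0, -2.0]))
        assert np.allclose(p.data, expect, atol=1e-6)

    def test_plateau_halves_after_patience(self):
        p = Tensor(np.zeros(1), requires_grad=True)
        opt = nn.AdamW([p], lr=1.0)
        sched = nn.ReduceLROnPlateau(opt, factor=0.5, patience=3)
        sched.step(1.0)        # first value becomes best
        for _ in range(2):
            sched.step(1.0)
        assert opt.lr == 1.0   # only 2 bad epochs so far
        sched.step(1.0)        # third consecutive non-improving epoch
        assert opt.lr == 0.5

    def test_plateau_resets_on_improvement(self):
        p = Tensor(np.zeros(1), requires_grad=True)
        opt = nn.AdamW([p], lr=1.0)
        sched = nn.ReduceLROnPlateau(opt, factor=0.5, patience=3)
        for v in [1.0, 1.0, 1.0, 0.5, 1.0, 1.0]:
            sched.step(v)
        assert opt.lr == 1.0
        sched.step(1.0)
        assert opt.lr == 0.5


class TestModule:
    def test_state_dict_roundtrip(self):
        rng = np.random.default_rng(0)

        class Net(nn.Module):
            def __init__(self):
                super().__init__()
                self.conv = nn.Conv2d(1, 2, 3, rng)
                self.bn = nn.BatchNorm2d(2)

            def __call__(self, x):
                return self.bn(self.conv(x))

        net = Net()
        net(Tensor(rng.standard_normal((1, 1, 4, 4)).astype(np.float32)))
        state = net.state_dict()
        net2 = Net()
        net2.load_state_dict(state)
        for (k1, v1), (k2, v2) in zip(sorted(net.state_dict().items()),
                                      sorted(net2.state_dict().items())):
            assert k1 == k2
            assert np.array_equal(v1, v2)
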