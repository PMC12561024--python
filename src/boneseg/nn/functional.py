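"""Fused neural-network operations with hand-derived backward passes.

Convolutions are im2col + GEMM so the heavy lifting happens inside BLAS;
backward passes reuse the stored column matrix.  All ops consume and
produce NCHW tensors.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

from .autodiff import as_tensor, make_op

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


# ----------------------------------------------------------------------
# convolution family
# ----------------------------------------------------------------------

def conv2d(x, weight, bias, stride=1, pad=1):
    """2-D cross-correlation, NCHW, square kernel, symmetric zero padding."""
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    xd = x.data
    n, c, h, w = xd.shape
    cout, cin, kh, kw = weight.data.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cin}")
    if pad:
        xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    else:
        xp = xd
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * oh * ow, c * kh * kw)
    wm = weight.data.reshape(cout, -1)
    y = cols @ wm.T
    y += bias.data
    out = np.ascontiguousarray(y.reshape(n, oh, ow, cout).transpose(0, 3, 1, 2))

    def build():
        def backward(g):
            gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
            dw = (gm.T @ cols).reshape(weight.data.shape)
            db = gm.sum(axis=0)
            dcols = (gm @ wm).reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for ki in range(kh):
                for kj in range(kw):
                    dxp[:, :, ki:ki + stride * oh:stride,
                        kj:kj + stride * ow:stride] += dcols[..., ki, kj]
            dx = dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp
            return dx, dw, db
        return backward

    return make_op(out, (x, weight, bias), build)


def dwconv3x3(x, weight, bias):
    """Depthwise 3x3 convolution (stride 1, pad 1); weight shape (C, 3, 3)."""
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    xd = x.data
    n, c, h, w = xd.shape
    xp = np.pad(xd, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros_like(xd)
    wd = weight.data
    for ki in range(3):
        for kj in range(3):
            out += wd[:, ki, kj][None, :, None, None] * xp[:, :, ki:ki + h, kj:kj + w]
    out += bias.data[None, :, None, None]

    def build():
        def backward(g):
            dw = np.empty_like(wd)
            for ki in range(3):
                for kj in range(3):
                    dw[:, ki, kj] = np.einsum(
                        "nchw,nchw->c", g, xp[:, :, ki:ki + h, kj:kj + w])
            db = g.sum(axis=(0, 2, 3))
            dxp = np.zeros_like(xp)
            for ki in range(3):
                for kj in range(3):
                    dxp[:, :, ki:ki + h, kj:kj + w] += (
                        wd[:, ki, kj][None, :, None, None] * g)
            return dxp[:, :, 1:1 + h, 1:1 + w], dw, db
        return backward

    return make_op(out, (x, weight, bias), build)


def linear_channels(x, weight, bias):
    """Per-pixel linear map over the channel axis (token MLP 'fc' layer).

    weight: (C_out, C_in); equivalent to a 1x1 convolution.
    """
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    xd = x.data
    n, c, h, w = xd.shape
    cout = weight.data.shape[0]
    xt = np.ascontiguousarray(xd.transpose(0, 2, 3, 1)).reshape(-1, c)
    y = xt @ weight.data.T
    y += bias.data
    out = np.ascontiguousarray(y.reshape(n, h, w, cout).transpose(0, 3, 1, 2))

    def build():
        def backward(g):
            gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
            dw = gm.T @ xt
            db = gm.sum(axis=0)
            dx = (gm @ weight.data).reshape(n, h, w, c).transpose(0, 3, 1, 2)
            return np.ascontiguousarray(dx), dw, db
        return backward

    return make_op(out, (x, weight, bias), build)


# ----------------------------------------------------------------------
# pooling / resampling
# ----------------------------------------------------------------------

def maxpool2x2(x):
    x = as_tensor(x)
    xd = x.data
    n, c, h, w = xd.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dims")
    oh, ow = h // 2, w // 2
    xr = np.ascontiguousarray(
        xd.reshape(n, c, oh, 2, ow, 2).transpose(0, 1, 2, 4, 3, 5)
    ).reshape(n, c, oh, ow, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def build():
        def backward(g):
            dxr = np.zeros((n, c, oh, ow, 4), dtype=g.dtype)
            np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
            dx = dxr.reshape(n, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            return (np.ascontiguousarray(dx).reshape(n, c, h, w),)
        return backward

    return make_op(out, (x,), build)


def _up_axis(a, axis):
    a = np.moveaxis(a, axis, -1)
    prev = np.concatenate([a[..., :1], a[..., :-1]], axis=-1)
    nxt = np.concatenate([a[..., 1:], a[..., -1:]], axis=-1)
    out = np.empty(a.shape[:-1] + (2 * a.shape[-1],), dtype=a.dtype)
    out[..., 0::2] = 0.25 * prev + 0.75 * a
    out[..., 1::2] = 0.75 * a + 0.25 * nxt
    return np.moveaxis(out, -1, axis)


def _up_axis_T(g, axis):
    g = np.moveaxis(g, axis, -1)
    ge = g[..., 0::2]
    go = g[..., 1::2]
    dx = 0.75 * (ge + go)
    dx[..., 1:] += 0.25 * go[..., :-1]
    dx[..., -1] += 0.25 * go[..., -1]
    dx[..., :-1] += 0.25 * ge[..., 1:]
    dx[..., 0] += 0.25 * ge[..., 0]
    return np.moveaxis(dx, -1, axis)


def upsample2x_bilinear(x):
    """Bilinear 2x upsampling with half-pixel centers (align_corners=False)."""
    x = as_tensor(x)
    out = _up_axis(_up_axis(x.data, 2), 3)

    def build():
        def backward(g):
            return (_up_axis_T(_up_axis_T(g, 3), 2),)
        return backward

    return make_op(out, (x,), build)


def pool3(x, axis, mode):
    """Size-3, stride-1 max/min pool along one spatial axis (same padding).

    Padding uses -inf (max) / +inf (min) so the border behaves as in the
    usual sliding-window pooling of probability maps.
    """
    x = as_tensor(x)
    xd = np.moveaxis(x.data, axis, -1)
    n = xd.shape[-1]
    fill = -np.inf if mode == "max" else np.inf
    xp = np.concatenate(
        [np.full(xd.shape[:-1] + (1,), fill, dtype=xd.dtype), xd,
         np.full(xd.shape[:-1] + (1,), fill, dtype=xd.dtype)], axis=-1)
    cand = np.stack([xp[..., 0:n], xp[..., 1:n + 1], xp[..., 2:n + 2]])
    arg = cand.argmax(axis=0) if mode == "max" else cand.argmin(axis=0)
    out = np.take_along_axis(cand, arg[None], axis=0)[0]
    out = np.moveaxis(out, -1, axis)

    def build():
        def backward(g):
            gm = np.moveaxis(g, axis, -1)
            dxp = np.zeros(xp.shape, dtype=gm.dtype)
            for k in range(3):
                dxp[..., k:k + n] += gm * (arg == k)
            dx = dxp[..., 1:n + 1]
            return (np.moveaxis(dx, -1, axis),)
        return backward

    return make_op(out, (x,), build)


def group_spatial_shift(x, axis, n_groups=5, max_shift=2):
    """Shift channel groups spatially by -max_shift..+max_shift (zero fill).

    The token-mixing trick of the shifted-MLP block: channels are split into
    ``n_groups`` chunks, chunk g is translated by ``g - max_shift`` pixels
    along ``axis`` with zeros shifted in at the border.
    """
    x = as_tensor(x)
    xd = x.data
    c = xd.shape[1]
    bounds = np.linspace(0, c, n_groups + 1).astype(int)
    shifts = list(range(-max_shift, n_groups - max_shift))
    out = np.zeros_like(xd)
    for g_i, s in enumerate(shifts):
        sl = slice(bounds[g_i], bounds[g_i + 1])
        out[:, sl] = _shift_fill(xd[:, sl], s, axis)

    def build():
        def backward(g):
            dx = np.zeros_like(g)
            for g_i, s in enumerate(shifts):
                sl = slice(bounds[g_i], bounds[g_i + 1])
                dx[:, sl] = _shift_fill(g[:, sl], -s, axis)
            return (dx,)
        return backward

    return make_op(out, (x,), build)


def _shift_fill(a, s, axis):
    """Translate by s along axis, filling vacated entries with zero."""
    if s == 0:
        return a.copy()
    out = np.zeros_like(a)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if s > 0:
        dst[axis] = slice(s, None)
        src[axis] = slice(None, -s)
    else:
        dst[axis] = slice(None, s)
        src[axis] = slice(-s, None)
    out[tuple(dst)] = a[tuple(src)]
    return out


# ----------------------------------------------------------------------
# normalisation / activations
# ----------------------------------------------------------------------

def batchnorm2d(x, gamma, beta, running_mean, running_var, training,
                momentum=0.1, eps=1e-5):
    """Batch normalisation over (N, H, W) per channel.

    ``running_mean``/``running_var`` are plain arrays updated in place in
    training mode (unbiased variance, matching the usual convention).
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    xd = x.data
    n, c, h, w = xd.shape
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        cnt = n * h * w
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (cnt / max(cnt - 1, 1))
    else:
        mu = running_mean
        var = running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu[None, :, None, None]) * invstd[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def build():
        def backward(g):
            dgamma = np.einsum("nchw,nchw->c", g, xhat)
            dbeta = g.sum(axis=(0, 2, 3))
            gx = g * gamma.data[None, :, None, None]
            if training:
                m1 = gx.mean(axis=(0, 2, 3), keepdims=True)
                m2 = (gx * xhat).mean(axis=(0, 2, 3), keepdims=True)
                dx = invstd[None, :, None, None] * (gx - m1 - xhat * m2)
            else:
                dx = gx * invstd[None, :, None, None]
            return dx.astype(g.dtype, copy=False), dgamma, dbeta
        return backward

    return make_op(out.astype(xd.dtype, copy=False), (x, gamma, beta), build)


def layernorm_channels(x, gamma, beta, eps=1e-6):
    """Layer normalisation over the channel axis, per spatial location."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    xd = x.data
    c = xd.shape[1]
    mu = xd.mean(axis=1, keepdims=True)
    var = xd.var(axis=1, keepdims=True)
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * invstd
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def build():
        def backward(g):
            dgamma = np.einsum("nchw,nchw->c", g, xhat)
            dbeta = g.sum(axis=(0, 2, 3))
            gx = g * gamma.data[None, :, None, None]
            m1 = gx.mean(axis=1, keepdims=True)
            m2 = (gx * xhat).mean(axis=1, keepdims=True)
            dx = invstd * (gx - m1 - xhat * m2)
            return dx.astype(g.dtype, copy=False), dgamma, dbeta
        return backward

    return make_op(out.astype(xd.dtype, copy=False), (x, gamma, beta), build)


def gelu(x):
    """Exact (erf-based) Gaussian error linear unit."""
    x = as_tensor(x)
    xd = x.data
    phi = 0.5 * (1.0 + erf(xd * _INV_SQRT2))
    out = xd * phi

    def build():
        def backward(g):
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * xd * xd)
            return (g * (phi + xd * pdf),)
        return backward

    return make_op(out.astype(xd.dtype, copy=False), (x,), build)


# ----------------------------------------------------------------------
# loss kernels
# ----------------------------------------------------------------------

def weighted_bce_with_logits(logits, target, pos_weight):
    """Mean pixel-wise binary cross-entropy on logits.

    The positive-class term is multiplied by ``pos_weight``:
    ``l = pw*t*softplus(-z) + (1-t)*softplus(z)``, averaged over all pixels.
    """
    logits = as_tensor(logits)
    z = logits.data
    t = np.asarray(target, dtype=z.dtype)
    if t.shape != z.shape:
        raise ValueError(f"shape mismatch: logits {z.shape} vs target {t.shape}")
    sp_pos = np.logaddexp(0.0, -z)   # softplus(-z) = -log sigmoid(z)
    sp_neg = np.logaddexp(0.0, z)    # softplus(z)  = -log(1 - sigmoid(z))
    pw = float(pos_weight)
    loss = (pw * t * sp_pos + (1.0 - t) * sp_neg).mean()

    def build():
        def backward(g):
            s = _sigmoid_np(z)
            dz = (-pw * t * (1.0 - s) + (1.0 - t) * s) * (g / z.size)
            return (dz.astype(z.dtype, copy=False),)
        return backward

    return make_op(np.asarray(loss, dtype=z.dtype), (logits,), build)


def _sigmoid_np(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
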