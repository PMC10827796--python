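"""Spatial ops (convolution, pooling, resize) as custom autodiff nodes.

Convolution uses an im2col lowering so the inner loop is a single BLAS
matmul; the backward pass scatters gradients back with a small kernel-offset
loop rather than ``np.add.at`` (orders of magnitude faster).  1x1 convolutions
bypass im2col entirely.  All spatial layouts are NCHW.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "conv2d",
    "max_pool2d",
    "avg_pool2d",
    "resize_nearest",
    "softmax",
    "log_softmax",
]


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int, ph: int, pw: int):
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    n, c, h, w = x.shape
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    s0, s1, s2, s3 = x.strides
    win = np.lib.stride_tricks.as_strided(
        x, (n, c, kh, kw, oh, ow), (s0, s1, s2, s3, s2 * sh, s3 * sw)
    )
    return np.ascontiguousarray(win).reshape(n, c * kh * kw, oh * ow), (oh, ow)


def _col2im(dcols: np.ndarray, xshape, kh, kw, sh, sw, ph, pw, oh, ow):
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=np.float32)
    dcols = dcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw] += dcols[:, :, i, j]
    if ph or pw:
        return dxp[:, :, ph : ph + h, pw : pw + w]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int | tuple[int, int] = 1, padding: int | tuple[int, int] = 0) -> Tensor:
    """2-D cross-correlation. ``weight``: (C_out, C_in, kh, kw)."""
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    co, ci, kh, kw = weight.data.shape
    n = x.data.shape[0]

    if kh == kw == 1 and sh == sw == 1 and ph == pw == 0:
        # pointwise fast path: batched matmul over flattened pixels
        n_, _, h, w = x.data.shape
        w2 = weight.data.reshape(co, ci)
        x3 = np.ascontiguousarray(x.data).reshape(n_, ci, h * w)
        out = np.matmul(w2, x3).reshape(n_, co, h, w)
        if bias is not None:
            out += bias.data.reshape(1, co, 1, 1)

        def backward(grad):
            g3 = np.ascontiguousarray(grad).reshape(n_, co, h * w)
            if weight.requires_grad:
                gw = np.tensordot(g3, x3, axes=([0, 2], [0, 2]))
                weight._accum(gw.reshape(co, ci, 1, 1))
            if bias is not None and bias.requires_grad:
                bias._accum(grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                x._accum(np.matmul(w2.T, g3).reshape(n_, ci, h, w))

        parents = (x, weight) if bias is None else (x, weight, bias)
        return Tensor._make(out, parents, backward)

    cols, (oh, ow) = _im2col(x.data, kh, kw, sh, sw, ph, pw)  # (n, ci*kh*kw, L)
    w2 = weight.data.reshape(co, ci * kh * kw)
    out = np.matmul(w2, cols).reshape(n, co, oh, ow)
    if bias is not None:
        out += bias.data.reshape(1, co, 1, 1)

    def backward(grad):
        g2 = np.ascontiguousarray(grad).reshape(n, co, oh * ow)
        if weight.requires_grad:
            gw = np.tensordot(g2, cols, axes=([0, 2], [0, 2]))
            weight._accum(gw.reshape(co, ci, kh, kw))
        if bias is not None and bias.requires_grad:
            bias._accum(grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(w2.T, g2)
            x._accum(_col2im(dcols, x.data.shape, kh, kw, sh, sw, ph, pw, oh, ow))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, backward)


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    k, s, p = kernel, stride or kernel, padding
    xd = x.data
    if p:
        xd = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
    n, c, h, w = xd.shape
    oh = (h - k) // s + 1
    ow = (w - k) // s + 1
    s0, s1, s2, s3 = xd.strides
    win = np.lib.stride_tricks.as_strided(
        xd, (n, c, oh, ow, k, k), (s0, s1, s2 * s, s3 * s, s2, s3)
    ).reshape(n, c, oh, ow, k * k)
    arg = win.argmax(axis=-1)
    out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def backward(grad):
        if not x.requires_grad:
            return
        dxp = np.zeros((n, c, h, w), dtype=np.float32)
        ki, kj = np.unravel_index(arg, (k, k))
        oi = np.arange(oh)[None, None, :, None] * s + ki
        oj = np.arange(ow)[None, None, None, :] * s + kj
        ni = np.arange(n)[:, None, None, None]
        ci_ = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (ni, ci_, oi, oj), grad)
        if p:
            dxp = dxp[:, :, p : p + x.data.shape[2], p : p + x.data.shape[3]]
        x._accum(dxp)

    return Tensor._make(out, (x,), backward)


def avg_pool2d(x: Tensor, kernel: int, stride: int | None = None) -> Tensor:
    """Non-padded average pooling; trailing rows/cols that do not fill a
    window are dropped (floor semantics, matching stride-2 transition pools
    on odd sizes, e.g. 47 -> 23)."""
    k, s = kernel, stride or kernel
    if s != k:
        raise NotImplementedError("only stride == kernel average pooling is used")
    n, c, h, w = x.data.shape
    oh, ow = h // k, w // k
    cropped = x.data[:, :, : oh * k, : ow * k]
    out = cropped.reshape(n, c, oh, k, ow, k).mean(axis=(3, 5))

    def backward(grad):
        if not x.requires_grad:
            return
        g = np.zeros_like(x.data)
        g[:, :, : oh * k, : ow * k] = np.repeat(
            np.repeat(grad, k, axis=2), k, axis=3
        ) / (k * k)
        x._accum(g)

    return Tensor._make(out, (x,), backward)


def resize_nearest(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Nearest-neighbour resize to ``size`` = (out_h, out_w)."""
    n, c, h, w = x.data.shape
    oh, ow = size
    ri = np.minimum((np.arange(oh) * h) // oh, h - 1)
    ci = np.minimum((np.arange(ow) * w) // ow, w - 1)
    out = x.data[:, :, ri[:, None], ci[None, :]]

    def backward(grad):
        if not x.requires_grad:
            return
        # reduce duplicated rows then duplicated cols
        tmp = np.zeros((n, c, h, ow), dtype=np.float32)
        np.add.at(tmp, (slice(None), slice(None), ri), grad)
        g = np.zeros((n, c, h, w), dtype=np.float32)
        np.add.at(g.transpose(3, 0, 1, 2), ci, tmp.transpose(3, 0, 1, 2))
        x._accum(g)

    return Tensor._make(out, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()
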