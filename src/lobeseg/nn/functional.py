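"""Spatial operators (convolution, pooling, resampling) with explicit adjoints.

Convolution is evaluated as im2col + BLAS matmul; its backward pass scatters
the column gradient back with one slice-add per kernel tap, so no Python loop
ever runs over pixels.  All operators assume NCHW layout.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


def _im2col(xp: np.ndarray, kh: int, kw: int, oh: int, ow: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N, C*kh*kw, oh*ow) column matrix (stride 1)."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh * kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i * kw + j] = xp[:, :, i : i + oh, j : j + ow]
    return cols.reshape(n, c * kh * kw, oh * ow)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, padding: int = 1) -> Tensor:
    """Stride-1 2D convolution (cross-correlation), NCHW.

    weight: (C_out, C_in, kh, kw); `padding` zero-pads both spatial axes.
    """
    n, c, h, w = x.shape
    co, ci, kh, kw = weight.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input has {c}, weight expects {ci}")
    oh, ow = h + 2 * padding - kh + 1, w + 2 * padding - kw + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = _im2col(xp, kh, kw, oh, ow)  # (N, K, L)
    wm = weight.data.reshape(co, ci * kh * kw)
    y = np.matmul(wm, cols).reshape(n, co, oh, ow)
    if bias is not None:
        y += bias.data.reshape(1, co, 1, 1)

    needs_grad = x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad)

    def backward(g):
        gm = g.reshape(n, co, oh * ow)
        if weight.requires_grad:
            dw = np.matmul(gm, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(dw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(gm.sum(axis=(0, 2)).reshape(bias.shape))
        if x.requires_grad:
            dcols = np.matmul(wm.T, gm).reshape(n, ci, kh * kw, oh, ow)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + oh, j : j + ow] += dcols[:, :, i * kw + j]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(y, parents, backward, requires_grad=needs_grad)


def max_pool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2. Spatial dims must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2 requires even spatial dims, got {(h, w)}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dxr = np.zeros_like(xr)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accumulate(dx)

    return Tensor._make(y, (x,), backward)


def _linear_coeffs(out_len: int, in_len: int, scale: float):
    """Source indices/weights for 1D linear interpolation (half-pixel centers)."""
    src = (np.arange(out_len) + 0.5) / scale - 0.5
    src = np.clip(src, 0, in_len - 1)
    i0 = np.floor(src).astype(np.intp)
    i1 = np.minimum(i0 + 1, in_len - 1)
    w1 = (src - i0).astype(np.float32)
    return i0, i1, w1


def upsample_bilinear2(x: Tensor) -> Tensor:
    """Bilinear 2x spatial upsampling (half-pixel alignment), NCHW."""
    n, c, h, w = x.shape
    oh, ow = 2 * h, 2 * w
    ry0, ry1, wy = _linear_coeffs(oh, h, 2.0)
    rx0, rx1, wx = _linear_coeffs(ow, w, 2.0)
    rows = x.data[:, :, ry0, :] * (1 - wy)[None, None, :, None] + x.data[:, :, ry1, :] * wy[None, None, :, None]
    y = rows[:, :, :, rx0] * (1 - wx) + rows[:, :, :, rx1] * wx

    def backward(g):
        if not x.requires_grad:
            return
        drows = np.zeros((n, c, oh, w), dtype=g.dtype)
        np.add.at(drows, (slice(None), slice(None), slice(None), rx0), g * (1 - wx))
        np.add.at(drows, (slice(None), slice(None), slice(None), rx1), g * wx)
        dx = np.zeros((n, c, h, w), dtype=g.dtype)
        np.add.at(dx, (slice(None), slice(None), ry0), drows * (1 - wy)[None, None, :, None])
        np.add.at(dx, (slice(None), slice(None), ry1), drows * wy[None, None, :, None])
        x._accumulate(dx)

    return Tensor._make(y, (x,), backward)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W); updates running stats in place."""
    axes = (0, 2, 3) if x.ndim == 4 else (0,)
    shape = (1, -1, 1, 1) if x.ndim == 4 else (1, -1)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(shape)) * inv_std.reshape(shape)
    y = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

    m = x.data.size // x.shape[1]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes).reshape(gamma.shape))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes).reshape(beta.shape))
        if x.requires_grad:
            gs = gamma.data.reshape(shape) * inv_std.reshape(shape)
            if training:
                dxhat = g * gamma.data.reshape(shape)
                t1 = dxhat.sum(axis=axes, keepdims=True)
                t2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
                dx = (dxhat - t1 / m - xhat * t2 / m) * inv_std.reshape(shape)
            else:
                dx = g * gs
            x._accumulate(dx)

    return Tensor._make(y, (x, gamma, beta), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout: scales kept units by 1/(1-p) during training."""
    if not training or p == 0.0:
        return x
    mask = (rng.random(x.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    out = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._make(out, (x,), backward)
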