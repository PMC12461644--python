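"""Convolutional primitives on the autodiff tape.

Dense convolutions use an explicit im2col + BLAS matmul (one contiguous copy
of the patch matrix, reused by the backward pass); depthwise convolutions
accumulate over kernel offsets directly on strided views, which avoids
copying the window tensor altogether.  The per-sample variants are the
workhorse of hyper-convolutions, where every element of a batch carries its
own generated kernel bank.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = ["conv2d", "depthwise_conv2d", "conv2d_batched",
           "depthwise_conv2d_batched", "upsample_nearest2x",
           "upsample_bilinear2x"]


def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _im2col(xp: np.ndarray, k: int, s: int) -> tuple[np.ndarray, int, int]:
    """(B,C,Hp,Wp) -> contiguous (B, Ho, Wo, C*k*k) patch matrix."""
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    B, C, Ho, Wo = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B, Ho, Wo, C * k * k)
    return cols, Ho, Wo


def _col2im(gcols: np.ndarray, xp_shape, k: int, s: int, Ho: int, Wo: int) -> np.ndarray:
    """(B, Ho, Wo, C*k*k) gradients -> (B,C,Hp,Wp) scatter-add."""
    B, C = xp_shape[0], xp_shape[1]
    g6 = gcols.reshape(B, Ho, Wo, C, k, k)
    gxp = np.zeros(xp_shape, dtype=gcols.dtype)
    for i in range(k):
        for j in range(k):
            gxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += \
                g6[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return gxp


def _fft_corr(a: np.ndarray, b: np.ndarray, contract: str,
              out_offset: tuple[int, int], out_size: tuple[int, int]) -> np.ndarray:
    """Linear 2D convolution of ``a`` with ``b`` over the last two axes via FFT,
    contracting channels per the einsum signature ``contract``; returns the
    window of the full convolution starting at ``out_offset``."""
    from scipy import fft as sfft

    Hf = sfft.next_fast_len(a.shape[-2] + b.shape[-2] - 1)
    Wf = sfft.next_fast_len(a.shape[-1] + b.shape[-1] - 1)
    Fa = sfft.rfft2(a, s=(Hf, Wf))
    Fb = sfft.rfft2(b, s=(Hf, Wf))
    Fy = np.einsum(contract, Fa, Fb, optimize=True)
    y = sfft.irfft2(Fy, s=(Hf, Wf))
    i, j = out_offset
    h, w = out_size
    return np.ascontiguousarray(y[..., i:i + h, j:j + w])


def _conv2d_fft(x: Tensor, w: Tensor, b: Tensor | None, padding: int) -> Tensor:
    """Stride-1 convolution via FFT (exact); pays off for larger kernels."""
    xd, wd = x.data, w.data
    B, C, H, W = xd.shape
    O, _, k, _ = wd.shape
    xp = _pad_hw(xd, padding)
    Hp, Wp = xp.shape[-2:]
    Ho, Wo = Hp - k + 1, Wp - k + 1
    wf = wd[:, :, ::-1, ::-1]
    out = _fft_corr(xp, wf, "bchw,ochw->bohw", (k - 1, k - 1), (Ho, Wo))
    out = out.astype(xd.dtype, copy=False)
    if b is not None:
        out = out + b.data[:, None, None]

    def backward(g):
        if w.requires_grad:
            gw = _fft_corr(xp, g[:, :, ::-1, ::-1], "bchw,bohw->ochw",
                           (Ho - 1, Wo - 1), (k, k))
            w._accumulate(gw.astype(wd.dtype, copy=False))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = _fft_corr(g, wd, "bohw,ochw->bchw", (0, 0), (Hp, Wp))
            gx = gxp[:, :, padding:padding + H, padding:padding + W] if padding else gxp
            x._accumulate(gx.astype(xd.dtype, copy=False))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def _conv2d_1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Pointwise convolution as a channel matmul (no patch copies)."""
    xd = x.data
    B, C, H, W = xd.shape
    O = w.data.shape[0]
    wf = w.data.reshape(O, C)
    out = np.matmul(wf, xd.reshape(B, C, H * W)).reshape(B, O, H, W)
    if b is not None:
        out += b.data[:, None, None]

    def backward(g):
        gf = g.reshape(B, O, H * W)
        if w.requires_grad:
            gw = np.einsum("bof,bcf->oc", gf, xd.reshape(B, C, H * W),
                           optimize=True)
            w._accumulate(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accumulate(np.matmul(wf.T, gf).reshape(B, C, H, W))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def _conv2d_batched_1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Per-sample pointwise convolution as batched channel matmuls."""
    xd = x.data
    B, C, H, W = xd.shape
    O = w.data.shape[1]
    wf = w.data.reshape(B, O, C)
    xf = xd.reshape(B, C, H * W)
    out = np.matmul(wf, xf).reshape(B, O, H, W)
    if b is not None:
        out += b.data[:, :, None, None]

    def backward(g):
        gf = g.reshape(B, O, H * W)
        if w.requires_grad:
            w._accumulate(np.matmul(gf, xf.transpose(0, 2, 1)).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(2, 3)))
        if x.requires_grad:
            x._accumulate(np.matmul(wf.transpose(0, 2, 1), gf).reshape(B, C, H, W))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """x: (B,C,H,W), w: (O,C,k,k), b: (O,) -> (B,O,H',W')."""
    xd, wd = x.data, w.data
    B, C, H, W = xd.shape
    O, _, k, _ = wd.shape
    if k == 1 and stride == 1 and padding == 0:
        return _conv2d_1x1(x, w, b)
    # the FFT path pays off once the im2col patch matrix gets large
    if stride == 1 and k >= 5 and H * W >= 1024 and C * k * k >= 256:
        return _conv2d_fft(x, w, b, padding)
    xp = _pad_hw(xd, padding)
    cols, Ho, Wo = _im2col(xp, k, stride)
    wf = wd.reshape(O, -1)
    out = (cols.reshape(-1, C * k * k) @ wf.T).reshape(B, Ho, Wo, O)
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if b is not None:
        out += b.data[:, None, None]

    def backward(g):
        gf = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, O)
        if w.requires_grad:
            w._accumulate((gf.T @ cols.reshape(-1, C * k * k)).reshape(wd.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = (gf @ wf).reshape(B, Ho, Wo, C * k * k)
            gxp = _col2im(gcols, xp.shape, k, stride, Ho, Wo)
            gx = gxp[:, :, padding:padding + H, padding:padding + W] if padding else gxp
            x._accumulate(gx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def conv2d_batched(x: Tensor, w: Tensor, b: Tensor | None = None,
                   stride: int = 1, padding: int = 0) -> Tensor:
    """Per-sample kernels. x: (B,C,H,W), w: (B,O,C,k,k), b: (B,O)."""
    xd, wd = x.data, w.data
    B, C, H, W = xd.shape
    _, O, _, k, _ = wd.shape
    if k == 1 and stride == 1 and padding == 0:
        return _conv2d_batched_1x1(x, w, b)
    xp = _pad_hw(xd, padding)
    cols, Ho, Wo = _im2col(xp, k, stride)          # (B,Ho,Wo,Ckk)
    colsf = cols.reshape(B, Ho * Wo, C * k * k)
    wf = wd.reshape(B, O, C * k * k)
    out = np.matmul(colsf, wf.transpose(0, 2, 1))  # (B, HoWo, O)
    out = np.ascontiguousarray(
        out.reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2))
    if b is not None:
        out += b.data[:, :, None, None]

    def backward(g):
        gf = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B, Ho * Wo, O)
        if w.requires_grad:
            w._accumulate(np.matmul(gf.transpose(0, 2, 1), colsf).reshape(wd.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(2, 3)))
        if x.requires_grad:
            gcols = np.matmul(gf, wf).reshape(B, Ho, Wo, C * k * k)
            gxp = _col2im(gcols, xp.shape, k, stride, Ho, Wo)
            gx = gxp[:, :, padding:padding + H, padding:padding + W] if padding else gxp
            x._accumulate(gx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 1, padding: int = 0) -> Tensor:
    """x: (B,C,H,W), w: (C,k,k), b: (C,) -> (B,C,H',W')."""
    xd, wd = x.data, w.data
    B, C, H, W = xd.shape
    _, k, _ = wd.shape
    xp = _pad_hw(xd, padding)
    Ho = (xp.shape[2] - k) // stride + 1
    Wo = (xp.shape[3] - k) // stride + 1
    out = np.zeros((B, C, Ho, Wo), dtype=xd.dtype)
    for i in range(k):
        for j in range(k):
            out += xp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] \
                * wd[None, :, i, j, None, None]
    if b is not None:
        out += b.data[:, None, None]

    def backward(g):
        if w.requires_grad:
            gw = np.empty_like(wd)
            for i in range(k):
                for j in range(k):
                    gw[:, i, j] = (g * xp[:, :, i:i + stride * Ho:stride,
                                          j:j + stride * Wo:stride]).sum(axis=(0, 2, 3))
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += \
                        g * wd[None, :, i, j, None, None]
            gx = gxp[:, :, padding:padding + H, padding:padding + W] if padding else gxp
            x._accumulate(gx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def depthwise_conv2d_batched(x: Tensor, w: Tensor, b: Tensor | None = None,
                             stride: int = 1, padding: int = 0) -> Tensor:
    """Per-sample depthwise kernels. x: (B,C,H,W), w: (B,C,k,k), b: (B,C)."""
    xd, wd = x.data, w.data
    B, C, H, W = xd.shape
    k = wd.shape[-1]
    xp = _pad_hw(xd, padding)
    Ho = (xp.shape[2] - k) // stride + 1
    Wo = (xp.shape[3] - k) // stride + 1
    out = np.zeros((B, C, Ho, Wo), dtype=xd.dtype)
    for i in range(k):
        for j in range(k):
            out += xp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] \
                * wd[:, :, i, j, None, None]
    if b is not None:
        out += b.data[:, :, None, None]

    def backward(g):
        if w.requires_grad:
            gw = np.empty_like(wd)
            for i in range(k):
                for j in range(k):
                    gw[:, :, i, j] = (g * xp[:, :, i:i + stride * Ho:stride,
                                             j:j + stride * Wo:stride]).sum(axis=(2, 3))
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += \
                        g * wd[:, :, i, j, None, None]
            gx = gxp[:, :, padding:padding + H, padding:padding + W] if padding else gxp
            x._accumulate(gx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def _up_axis_bilinear(x: Tensor, axis: int) -> Tensor:
    """Double one spatial axis with 2x bilinear interpolation (edges clamped)."""
    from .tensor import concatenate, stack

    n = x.shape[axis]
    sl = lambda a, b: tuple([slice(None)] * axis + [slice(a, b)])
    left = concatenate([x[sl(0, 1)], x[sl(0, n - 1)]], axis=axis)
    right = concatenate([x[sl(1, n)], x[sl(n - 1, n)]], axis=axis)
    even = x * 0.75 + left * 0.25
    odd = x * 0.75 + right * 0.25
    out = stack([even, odd], axis=axis + 1)
    new_shape = list(x.shape)
    new_shape[axis] = 2 * n
    return out.reshape(new_shape)


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear 2x upsampling of the last two axes (half-pixel convention)."""
    return _up_axis_bilinear(_up_axis_bilinear(x, x.ndim - 2), x.ndim - 1)


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of the last two axes."""
    xd = x.data
    out = xd.repeat(2, axis=-2).repeat(2, axis=-1)

    def backward(g):
        B, C, H2, W2 = g.shape
        x._accumulate(g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), backward)
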