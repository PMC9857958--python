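"""Convolution, pooling, normalization and loss primitives.

Convolutions are lowered to BLAS matrix products through an explicit
``im2col`` expansion (a loop over the K x K kernel offsets, each a strided
slice copy), which is the fastest pure-NumPy formulation on a single CPU
core.  1x1 convolutions skip the expansion entirely and run as one matmul.
Bilinear upsampling is separable and implemented as two small dense
interpolation-matrix products, so its transpose (the backward pass) is
exact.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "conv2d",
    "max_pool2d",
    "upsample_bilinear",
    "global_avg_pool",
    "global_avg_pool_upsampled",
    "batch_norm",
    "softmax",
    "cross_entropy",
    "interp_matrix",
]


# ---------------------------------------------------------------------------
# im2col helpers
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    b, c, h, w = x.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((b, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols, ho, wo


def _col2im(cols: np.ndarray, in_shape, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    b, c, h, w = in_shape
    ho, wo = cols.shape[-2:]
    out = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    if pad:
        out = out[:, :, pad : pad + h, pad : pad + w]
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation with square kernel, symmetric padding."""
    b, c, h, w = x.shape
    co, ci, kh, kw = weight.shape
    if ci != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {ci}")

    if kh == 1 and kw == 1 and pad == 0:
        # pure channel-mixing matmul; subsample first when strided
        xd = x.data[:, :, ::stride, ::stride] if stride > 1 else x.data
        _, _, ho, wo = xd.shape
        wmat = weight.data.reshape(co, c)
        out = (wmat @ xd.reshape(b, c, ho * wo)).reshape(b, co, ho, wo)

        def bw(g: np.ndarray) -> None:
            gmat = g.reshape(b, co, ho * wo)
            if weight.requires_grad:
                gw = np.matmul(gmat, xd.reshape(b, c, ho * wo).transpose(0, 2, 1)).sum(0)
                weight._accumulate(gw.reshape(co, c, 1, 1))
            if x.requires_grad:
                gx = (wmat.T @ gmat).reshape(b, c, ho, wo)
                if stride > 1:
                    full = np.zeros_like(x.data)
                    full[:, :, ::stride, ::stride] = gx
                    gx = full
                x._accumulate(gx)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))

        parents = (x, weight) if bias is None else (x, weight, bias)
        out_t = Tensor(out, parents=parents, backward=bw)
    else:
        cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
        k = c * kh * kw
        colmat = cols.reshape(b, k, ho * wo)
        wmat = weight.data.reshape(co, k)
        out = (wmat @ colmat).reshape(b, co, ho, wo)

        def bw(g: np.ndarray) -> None:
            gmat = g.reshape(b, co, ho * wo)
            if weight.requires_grad:
                gw = np.matmul(gmat, colmat.transpose(0, 2, 1)).sum(0)
                weight._accumulate(gw.reshape(co, c, kh, kw))
            if x.requires_grad:
                gcols = (wmat.T @ gmat).reshape(b, c, kh, kw, ho, wo)
                x._accumulate(_col2im(gcols, x.shape, kh, kw, stride, pad))
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))

        parents = (x, weight) if bias is None else (x, weight, bias)
        out_t = Tensor(out, parents=parents, backward=bw)

    if bias is not None:
        out_t.data += bias.data.reshape(1, co, 1, 1)
    return out_t


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, pad: int = 1) -> Tensor:
    b, c, h, w = x.shape
    if pad:
        # pad with -inf so padding never wins the max
        xp = np.full((b, c, h + 2 * pad, w + 2 * pad), -np.inf, dtype=x.data.dtype)
        xp[:, :, pad : pad + h, pad : pad + w] = x.data
    else:
        xp = x.data
    ho = (h + 2 * pad - kernel) // stride + 1
    wo = (w + 2 * pad - kernel) // stride + 1
    windows = np.empty((b, c, kernel * kernel, ho, wo), dtype=x.data.dtype)
    idx = 0
    for i in range(kernel):
        for j in range(kernel):
            windows[:, :, idx] = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
            idx += 1
    arg = windows.argmax(axis=2)
    out = np.take_along_axis(windows, arg[:, :, None], axis=2)[:, :, 0]

    def bw(g: np.ndarray) -> None:
        gcols = np.zeros_like(windows)
        np.put_along_axis(gcols, arg[:, :, None], g[:, :, None], axis=2)
        gcols = gcols.reshape(b, c, kernel, kernel, ho, wo)
        gx = _col2im(gcols, (b, c, h, w), kernel, kernel, stride, pad)
        x._accumulate(gx)

    return Tensor(out, parents=(x,), backward=bw)


# ---------------------------------------------------------------------------
# bilinear upsampling
# ---------------------------------------------------------------------------

def interp_matrix(n_in: int, factor: int) -> np.ndarray:
    """Dense (n_in*factor, n_in) 1-D bilinear interpolation matrix.

    Uses the half-pixel-center convention: output pixel o samples source
    coordinate (o + 0.5)/factor - 0.5, clamped at the borders.
    """
    n_out = n_in * factor
    mat = np.zeros((n_out, n_in), dtype=np.float32)
    for o in range(n_out):
        src = (o + 0.5) / factor - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        t = src - lo
        mat[o, lo] += 1.0 - t
        mat[o, hi] += t
    return mat


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    """Upsample the two trailing spatial axes by an integer factor."""
    b, c, h, w = x.shape
    ah = interp_matrix(h, factor)
    aw = interp_matrix(w, factor)
    out = ah @ x.data @ aw.T  # (B,C,H*f,W) then (B,C,H*f,W*f)

    def bw(g: np.ndarray) -> None:
        x._accumulate(ah.T @ g @ aw)

    return Tensor(out, parents=(x,), backward=bw)


def global_avg_pool(x: Tensor) -> Tensor:
    """Spatial mean: (B,C,H,W) -> (B,C)."""
    return x.mean(axis=(2, 3))


def global_avg_pool_upsampled(x: Tensor, factor: int) -> Tensor:
    """Spatial mean of ``upsample_bilinear(x, factor)`` without materializing it.

    The mean of a bilinearly upsampled map is a fixed linear functional of the
    source map (the column means of the interpolation matrices), so this is
    exactly equal to ``global_avg_pool(upsample_bilinear(x, factor))`` at a
    fraction of the memory and FLOPs.  Used by the classification head, where
    the fused map's spatial mean is all that is needed.
    """
    b, c, h, w = x.shape
    wh = interp_matrix(h, factor).mean(axis=0)  # (H,)
    ww = interp_matrix(w, factor).mean(axis=0)  # (W,)
    wmap = np.outer(wh, ww).astype(np.float32)  # (H,W)
    out = np.einsum("bchw,hw->bc", x.data, wmap)

    def bw(g: np.ndarray) -> None:
        x._accumulate(g[:, :, None, None] * wmap[None, None])

    return Tensor(out, parents=(x,), backward=bw)


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

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
    """Per-channel batch normalization over (B, H, W).

    In training mode batch statistics are used and the running buffers are
    updated in place; in eval mode the running buffers are used.  The
    backward pass is the standard closed form.
    """
    b, c, h, w = x.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n = b * h * w
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        # unbiased running variance, as is conventional
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bw(g: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
            if training:
                m = b * h * w
                gmean = g.mean(axis=(0, 2, 3))[None, :, None, None]
                gxhat_mean = (g * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
                x._accumulate(gs * (g - gmean - xhat * gxhat_mean))
            else:
                x._accumulate(gs * g)

    return Tensor(out, parents=(x, gamma, beta), backward=bw)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy for integer class labels."""
    labels = np.asarray(labels)
    b = logits.shape[0]
    p = softmax(logits.data)
    eps = 1e-12
    loss = -np.log(p[np.arange(b), labels] + eps).mean()

    def bw(g: np.ndarray) -> None:
        grad = p.copy()
        grad[np.arange(b), labels] -= 1.0
        logits._accumulate(grad * (float(g) / b))

    return Tensor(np.float32(loss), parents=(logits,), backward=bw)
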