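"""Differentiable operations for the segmentation network.

Convolutions are computed as im2col + BLAS matmul; the data gradient of a
stride-1 convolution is itself a stride-1 convolution with the spatially
flipped, channel-transposed kernel, so no scatter-add is needed anywhere on
the hot path.  All ops are dtype-preserving (float32 for training, float64
for finite-difference gradient checks).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

from .tensor import Tensor, as_tensor, grad_enabled

__all__ = [
    "add", "sub", "mul", "square", "log", "clip", "relu", "sigmoid",
    "mean", "sum", "reshape", "concat", "linear",
    "conv2d", "conv_transpose2d", "maxpool2x2", "reduce_max",
    "resize_linear", "rot90", "linear_resize_matrix",
]


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if grad_enabled() and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _node(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(-_unbroadcast(g, b.shape))

    return _node(a.data - b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(a.data * b.data, (a, b), backward)


def square(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(2.0 * a.data * g)

    return _node(a.data * a.data, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(g / a.data)

    return _node(np.log(a.data), (a,), backward)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    out = np.clip(a.data, lo, hi)
    inside = (a.data > lo) & (a.data < hi)

    def backward(g):
        a._accumulate(g * inside)

    return _node(out, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _node(a.data * mask, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    s = expit(a.data)

    def backward(g):
        a._accumulate(g * s * (1.0 - s))

    return _node(s, (a,), backward)


# ---------------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------------

def _norm_axes(axis, ndim):
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(a % ndim for a in axis)


def sum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:  # noqa: A001
    axes = _norm_axes(axis, a.ndim)
    out = a.data.sum(axis=axes, keepdims=keepdims)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        a._accumulate(np.broadcast_to(g, a.shape))

    return _node(out, (a,), backward)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    axes = _norm_axes(axis, a.ndim)
    n = int(np.prod([a.shape[i] for i in axes]))
    out = a.data.mean(axis=axes, keepdims=keepdims)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        a._accumulate(np.broadcast_to(g, a.shape) / n)

    return _node(out, (a,), backward)


def reduce_max(a: Tensor, axis, keepdims: bool = False) -> Tensor:
    axes = _norm_axes(axis, a.ndim)
    out = a.data.max(axis=axes, keepdims=True)
    mask = a.data == out  # ties share the gradient equally
    counts = mask.sum(axis=axes, keepdims=True)
    res = out if keepdims else out.squeeze(axes)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        a._accumulate(np.broadcast_to(g / counts, a.shape) * mask)

    return _node(res, (a,), backward)


def reshape(a: Tensor, shape) -> Tensor:
    def backward(g):
        a._accumulate(g.reshape(a.shape))

    return _node(a.data.reshape(shape), (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]
    ts = tuple(tensors)

    def backward(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return _node(np.concatenate(datas, axis=axis), ts, backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x (B, Ci) @ w (Ci, Co) + b."""
    out = x.data @ w.data
    if b is not None:
        out = out + b.data

    def backward(g):
        if x.requires_grad:
            x._accumulate(g @ w.data.T)
        if w.requires_grad:
            w._accumulate(x.data.T @ g)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int):
    """(B,C,H,W) -> (B, C*k*k, Ho*Wo) patch matrix for stride-1 convolution.

    Built from k*k shifted contiguous slices (fast) instead of a strided
    gather; column order is (c, kh, kw), matching w.reshape(Co, C*k*k).
    """
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    b, c, h, w = x.shape
    ho, wo = h - k + 1, w - k + 1
    if k == 1:
        return x.reshape(b, c, ho * wo), ho, wo
    cols = np.empty((b, c, k * k, ho, wo), dtype=x.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[:, :, ki * k + kj] = x[:, :, ki:ki + ho, kj:kj + wo]
    return cols.reshape(b, c * k * k, ho * wo), ho, wo


def _conv_fwd(x: np.ndarray, wmat: np.ndarray, k: int, pad: int):
    cols, ho, wo = _im2col(x, k, pad)
    out = np.matmul(wmat, cols)  # (B, Co, Ho*Wo)
    return out.reshape(x.shape[0], wmat.shape[0], ho, wo), cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int | None = None) -> Tensor:
    """Stride-1 2D convolution (cross-correlation); default 'same' padding."""
    co, ci, k, _ = w.shape
    if pad is None:
        pad = k // 2
    wmat = w.data.reshape(co, ci * k * k)
    out, cols = _conv_fwd(x.data, wmat, k, pad)
    if b is not None:
        out += b.data.reshape(1, co, 1, 1)

    def backward(g):
        gmat = g.reshape(g.shape[0], co, -1)  # (B, Co, Ho*Wo)
        if w.requires_grad:
            dw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)  # Co, C*k*k
            w._accumulate(dw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # data gradient = conv of g with flipped, channel-transposed kernel
            wt = w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
            dx, _ = _conv_fwd(g, np.ascontiguousarray(wt).reshape(ci, co * k * k), k, k - 1 - pad)
            x._accumulate(dx)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 2) -> Tensor:
    """Transposed convolution with kernel == stride (non-overlapping blocks).

    x: (B,Ci,H,W), w: (Ci,Co,s,s) -> (B,Co,H*s,W*s)
    """
    s = stride
    ci, co = w.shape[:2]
    bsz, _, h, wd = x.shape
    out = np.einsum("bihw,iokl->bohkwl", x.data, w.data, optimize=True)
    out = out.reshape(bsz, co, h * s, wd * s)
    if b is not None:
        out += b.data.reshape(1, co, 1, 1)

    def backward(g):
        gb = g.reshape(bsz, co, h, s, wd, s)
        if x.requires_grad:
            x._accumulate(np.einsum("bohkwl,iokl->bihw", gb, w.data, optimize=True))
        if w.requires_grad:
            w._accumulate(np.einsum("bihw,bohkwl->iokl", x.data, gb, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    b, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    xr = x.data.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(b, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dxr = np.zeros_like(xr)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(dx.reshape(b, c, h, w))

    return _node(out, (x,), backward)


# ---------------------------------------------------------------------------
# geometric ops (used to align perturbed-branch predictions)
# ---------------------------------------------------------------------------

def linear_resize_matrix(n_out: int, n_in: int, dtype=np.float64) -> np.ndarray:
    """Dense 1D linear-interpolation matrix A with out = A @ in.

    Half-pixel-centre convention (align_corners=False), edges clamped.
    Row sums are exactly 1, so constants are preserved.
    """
    a = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    a[np.arange(n_out), lo] += 1.0 - frac
    a[np.arange(n_out), hi] += frac
    return a


def resize_linear(x: Tensor, ah: np.ndarray, aw: np.ndarray) -> Tensor:
    """Bilinear resize of the trailing two axes via out = Ah @ x @ Aw^T."""
    ah = ah.astype(x.dtype, copy=False)
    aw = aw.astype(x.dtype, copy=False)
    out = np.matmul(np.matmul(ah, x.data), aw.T)

    def backward(g):
        x._accumulate(np.matmul(np.matmul(ah.T, g), aw))

    return _node(out, (x,), backward)


def rot90(x: Tensor, k: int) -> Tensor:
    """Rotate the trailing two axes by k*90 degrees (exact pixel permutation)."""
    out = np.ascontiguousarray(np.rot90(x.data, k, axes=(-2, -1)))

    def backward(g):
        x._accumulate(np.ascontiguousarray(np.rot90(g, -k, axes=(-2, -1))))

    return _node(out, (x,), backward)


def as_float_tensor(x, dtype=np.float32) -> Tensor:
    return as_tensor(np.asarray(x, dtype=dtype))
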