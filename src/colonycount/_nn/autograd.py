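"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is a small tape-based engine providing exactly the operations the
segmentation and counting networks need: dense and 2-D convolutional
layers, pooling, nearest-neighbour upsampling, channel concatenation,
batch normalization, ReLU, and numerically stable binary-cross-entropy /
softmax losses on logits.  Everything is float32 and fully deterministic
given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "relu",
    "matmul",
    "conv2d",
    "maxpool2d",
    "upsample_nearest",
    "concat",
    "global_avg_pool",
    "bce_with_logits",
    "softmax_cross_entropy",
    "sigmoid",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        """Run reverse-mode accumulation from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topological sort: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _wrap(data, parents, backward):
    return Tensor(data, parents=parents, backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise sum with broadcasting (used for bias and residual adds)."""
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _wrap(out_data, (a, b), backward)


def _unbroadcast(g, shape):
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return _wrap(out_data, (x,), backward)


def matmul(x: Tensor, w: Tensor) -> Tensor:
    """x (N, F) @ w (F, O)."""
    out_data = x.data @ w.data

    def backward(g):
        if x.requires_grad:
            x._accum(g @ w.data.T)
        if w.requires_grad:
            w._accum(x.data.T @ g)

    return _wrap(out_data, (x, w), backward)


# ---------------------------------------------------------------------------
# convolution via im2col

def _im2col(x, kh, kw, stride, dilation, pad):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hh, ww = x.shape[2], x.shape[3]
    eff_kh = (kh - 1) * dilation + 1
    eff_kw = (kw - 1) * dilation + 1
    oh = (hh - eff_kh) // stride + 1
    ow = (ww - eff_kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, oh, ow),
        strides=(s0, s1, s2 * dilation, s3 * dilation, s2 * stride, s3 * stride),
        writeable=False,
    )
    cols = np.ascontiguousarray(windows).reshape(n, c * kh * kw, oh * ow)
    return cols, oh, ow


def _col2im(cols, x_shape, kh, kw, stride, dilation, pad):
    n, c, h, w = x_shape
    hh, ww = h + 2 * pad, w + 2 * pad
    eff_kh = (kh - 1) * dilation + 1
    eff_kw = (kw - 1) * dilation + 1
    oh = (hh - eff_kh) // stride + 1
    ow = (ww - eff_kw) // stride + 1
    xg = np.zeros((n, c, hh, ww), dtype=np.float32)
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        hi = i * dilation
        for j in range(kw):
            wj = j * dilation
            xg[:, :, hi : hi + stride * oh : stride, wj : wj + stride * ow : stride] += cols[
                :, :, i, j
            ]
    if pad:
        xg = xg[:, :, pad : pad + h, pad : pad + w]
    return xg


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride=1,
           padding=0, dilation=1) -> Tensor:
    """2-D convolution (cross-correlation); w has shape (C_out, C_in, kh, kw)."""
    co, ci, kh, kw = w.data.shape
    cols, oh, ow = _im2col(x.data, kh, kw, stride, dilation, padding)
    w2 = w.data.reshape(co, -1)
    out = np.matmul(w2, cols)  # (O,F) @ (N,F,L) -> (N,O,L)
    out = out.reshape(x.data.shape[0], co, oh, ow)
    if b is not None:
        out = out + b.data.reshape(1, co, 1, 1)

    def backward(g):
        g2 = np.ascontiguousarray(g.reshape(g.shape[0], co, -1))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(dw.reshape(w.data.shape))
        if x.requires_grad:
            dcols = np.matmul(w2.T, g2)
            x._accum(_col2im(dcols, x.data.shape, kh, kw, stride, dilation, padding))

    parents = (x, w) if b is None else (x, w, b)
    return _wrap(out, parents, backward)


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"maxpool2d: spatial dims {(h, w)} not divisible by {k}")
    xr = x.data.reshape(n, c, h // k, k, w // k, k)
    win = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // k, w // k, k * k)
    out = win.max(axis=-1)
    first = win.argmax(axis=-1)  # first max wins on ties
    sel = np.zeros_like(win, dtype=bool)
    np.put_along_axis(sel, first[..., None], True, axis=-1)
    sel = sel.reshape(n, c, h // k, w // k, k, k)

    def backward(g):
        if x.requires_grad:
            gx = g[:, :, :, :, None, None] * sel
            x._accum(
                gx.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w).astype(np.float32)
            )

    return _wrap(out, (x,), backward)


def upsample_nearest(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Nearest-neighbour resize to ``size`` (used for in-network upsampling)."""
    n, c, h, w = x.data.shape
    oh, ow = size
    ri = (np.arange(oh) * h // oh).astype(np.intp)
    ci = (np.arange(ow) * w // ow).astype(np.intp)
    out = x.data[:, :, ri][:, :, :, ci]

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, (slice(None), slice(None), ri[:, None], ci[None, :]), g)
            x._accum(gx)

    return _wrap(out, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, gp in zip(tensors, parts):
            if t.requires_grad:
                t._accum(gp)

    return _wrap(out, tuple(tensors), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C)."""
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def backward(g):
        if x.requires_grad:
            x._accum(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))

    return _wrap(out, (x,), backward)


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Stable elementwise logistic on a plain array (inference only)."""
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softplus(z):
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


def bce_with_logits(logits: Tensor, target: np.ndarray,
                    pos_weight: np.ndarray | float = 1.0) -> Tensor:
    """Mean binary cross-entropy on logits with a weight on positive terms.

    loss = mean( w * t * softplus(-z) + (1 - t) * softplus(z) )

    With ``pos_weight == 1`` this is the standard BCE-with-logits.
    """
    t = np.asarray(target, dtype=np.float32)
    z = logits.data
    w = np.asarray(pos_weight, dtype=np.float32)
    per = w * t * _softplus(-z) + (1.0 - t) * _softplus(z)
    out = np.float32(per.mean())
    n = per.size

    def backward(g):
        if logits.requires_grad:
            sz = sigmoid(z)
            d = (-w * t * (1.0 - sz) + (1.0 - t) * sz) / n
            logits._accum(g * d.astype(np.float32))

    return _wrap(out, (logits,), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray,
                          class_weights: np.ndarray | None = None) -> Tensor:
    """Mean weighted softmax cross-entropy; labels are integer class ids."""
    z = logits.data.astype(np.float64)
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    idx = np.arange(n)
    w = (
        np.ones(n)
        if class_weights is None
        else np.asarray(class_weights, dtype=np.float64)[labels]
    )
    losses = -w * np.log(np.maximum(p[idx, labels], 1e-12))
    out = np.float32(losses.mean())

    def backward(g):
        if logits.requires_grad:
            d = p.copy()
            d[idx, labels] -= 1.0
            d *= w[:, None] / n
            logits._accum((g * d).astype(np.float32))

    return _wrap(out, (logits,), backward)
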