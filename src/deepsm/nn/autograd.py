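"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operations the denoiser needs: stride-1 same-padding
convolution (via im2col and BLAS matmuls), 2x2 max-pooling, nearest
up-sampling, elementwise nonlinearities, channel concat/split, row
gather, and mean-squared-error reduction.  Gradients are accumulated by a
topological-order backward sweep from a scalar loss.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "conv2d",
    "maxpool2x2",
    "upsample2x",
    "relu",
    "sigmoid",
    "tanh",
    "add",
    "sub",
    "mul",
    "concat",
    "split_channels",
    "take_rows",
    "mse",
]


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, data, parents=(), backward_fn=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.parents = parents
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node.backward_fn is not None and node.grad is not None:
                node.backward_fn(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _unary(x: Tensor, out_data, grad_fn) -> Tensor:
    out = Tensor(out_data, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(grad_fn(g))

    out.backward_fn = backward
    return out


# ---------------------------------------------------------------------------
# Convolution


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*k*k) patch matrix for stride-1 same conv."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = sliding_window_view(xp, (k, k), axis=(2, 3))  # B,C,H,W,k,k
    return windows.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-1, same-padding 2-D convolution (cross-correlation convention).

    ``x``: (B, C, H, W); ``weight``: (O, C, k, k) with odd k; ``bias``: (O,).
    """
    b, c, h, w = x.data.shape
    o, c_w, k, _ = weight.data.shape
    assert c == c_w, f"channel mismatch {c} vs {c_w}"
    pad = k // 2
    cols = _im2col(x.data, k, pad)                    # (BHW, Ckk)
    w_mat = weight.data.reshape(o, c * k * k)
    out_data = (cols @ w_mat.T).reshape(b, h, w, o).transpose(0, 3, 1, 2)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, parents=parents)

    def backward(g):
        g_mat = g.transpose(0, 2, 3, 1).reshape(b * h * w, o)  # (BHW, O)
        if weight.requires_grad:
            weight._accumulate((g_mat.T @ cols).reshape(o, c, k, k))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # grad wrt input = conv of g with spatially-flipped, transposed kernel
            w_flip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C,O,k,k)
            g_cols = _im2col(g, k, pad)                                   # (BHW, Okk)
            gx = (g_cols @ w_flip.reshape(c, o * k * k).T)
            x._accumulate(gx.reshape(b, h, w, c).transpose(0, 3, 1, 2))

    out.backward_fn = backward
    return out


# ---------------------------------------------------------------------------
# Pooling / resampling


def maxpool2x2(x: Tensor) -> Tensor:
    b, c, h, w = x.data.shape
    assert h % 2 == 0 and w % 2 == 0, "maxpool2x2 requires even dims"
    xr = (
        x.data.reshape(b, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(b, c, h // 2, w // 2, 4)
    )
    idx = np.argmax(xr, axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(xr)
        np.put_along_axis(gx, idx[..., None], g[..., None], axis=-1)
        gx = (
            gx.reshape(b, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, h, w)
        )
        x._accumulate(gx)

    out.backward_fn = backward
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor(out_data, parents=(x,))

    def backward(g):
        if x.requires_grad:
            b, c, h2, w2 = g.shape
            gx = g.reshape(b, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            x._accumulate(gx)

    out.backward_fn = backward
    return out


# ---------------------------------------------------------------------------
# Elementwise


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return _unary(x, x.data * mask, lambda g: g * mask)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))
    return _unary(x, s, lambda g: g * s * (1.0 - s))


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    return _unary(x, t, lambda g: g * (1.0 - t * t))


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    out.backward_fn = backward
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data - b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(-g)

    out.backward_fn = backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * b.data)
        if b.requires_grad:
            b._accumulate(g * a.data)

    out.backward_fn = backward
    return out


# ---------------------------------------------------------------------------
# Shape ops


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out.backward_fn = backward
    return out


def split_channels(x: Tensor, n_parts: int) -> list[Tensor]:
    """Split along the channel axis into equal parts."""
    c = x.data.shape[1]
    assert c % n_parts == 0
    step = c // n_parts
    parts = []
    for i in range(n_parts):
        lo = i * step
        part = Tensor(x.data[:, lo:lo + step], parents=(x,))

        def backward(g, lo=lo):
            if x.requires_grad:
                gx = np.zeros_like(x.data)
                gx[:, lo:lo + step] = g
                x._accumulate(gx)

        part.backward_fn = backward
        parts.append(part)
    return parts


def take_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows along axis 0 (backward scatter-adds)."""
    idx = np.asarray(idx)
    out = Tensor(x.data[idx], parents=(x,))

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, idx, g)
            x._accumulate(gx)

    out.backward_fn = backward
    return out


def mse(a: Tensor, b: Tensor) -> Tensor:
    """Mean squared error over all elements: (1/(N*M)) * sum((a-b)^2)."""
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch {a.data.shape} vs {b.data.shape}")
    diff = a.data - b.data
    out = Tensor(np.mean(diff * diff), parents=(a, b))
    scale = 2.0 / diff.size

    def backward(g):
        gd = g * scale * diff
        if a.requires_grad:
            a._accumulate(gd)
        if b.requires_grad:
            b._accumulate(-gd)

    out.backward_fn = backward
    return out
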