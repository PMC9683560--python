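"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` together with an optional gradient and a
closure that propagates gradients to its parents.  The op set is deliberately
small — exactly the operations the vessel-segmentation and grading networks
need (strided/dilated convolution, batch normalisation, leaky ReLU, channel
concatenation, bilinear x2 upsampling, linear layers, pooling and the loss
heads).  Gradients are dense numpy arrays; all computation is float32 unless
the caller supplies float64 (the finite-difference tests do).
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "batchnorm2d",
    "leaky_relu",
    "sigmoid",
    "softmax",
    "concat_channels",
    "upsample_bilinear2x",
    "linear",
    "global_avg_pool",
    "add",
    "scale",
]


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
        name: Optional[str] = None,
    ) -> None:
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this node through the whole graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def _needs_grad(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------

def _im2col_view(xp: np.ndarray, kh: int, kw: int, oh: int, ow: int,
                 stride: int, dilation: int) -> np.ndarray:
    """Strided (no-copy) view of shape (N, C, kh, kw, oh, ow)."""
    n, c, _, _ = xp.shape
    sn, sc, sh, sw = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, kh, kw, oh, ow),
        strides=(sn, sc, sh * dilation, sw * dilation, sh * stride, sw * stride),
        writeable=False,
    )


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None, *,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, square kernel."""
    xd, wd = x.data, w.data
    n, cin, h, wdt = xd.shape
    cout, cin_w, kh, kw = wd.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin} vs weight {cin_w}")
    if padding:
        xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = xd
    hp, wp = xp.shape[2], xp.shape[3]
    oh = (hp - dilation * (kh - 1) - 1) // stride + 1
    ow = (wp - dilation * (kw - 1) - 1) // stride + 1
    cols = _im2col_view(xp, kh, kw, oh, ow, stride, dilation)
    # (Cout, C, kh, kw) x (N, C, kh, kw, oh, ow) -> (Cout, N, oh, ow)
    y = np.tensordot(wd, cols, axes=([1, 2, 3], [1, 2, 3]))
    y = np.ascontiguousarray(y.transpose(1, 0, 2, 3))
    if b is not None:
        y += b.data[None, :, None, None]

    parents = [x, w] + ([b] if b is not None else [])
    if not _needs_grad(*parents):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        if w.requires_grad or w._parents:
            gw = np.tensordot(gy, cols, axes=([0, 2, 3], [0, 4, 5]))
            w.accumulate(gw)
        if b is not None and (b.requires_grad or b._parents):
            b.accumulate(gy.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gxp = np.zeros_like(xp)
            for ki in range(kh):
                for kj in range(kw):
                    # (N, oh, ow, C) contribution from kernel tap (ki, kj)
                    t = np.tensordot(gy, wd[:, :, ki, kj], axes=([1], [0]))
                    hi = ki * dilation
                    wi = kj * dilation
                    gxp[:, :, hi:hi + stride * oh:stride,
                        wi:wi + stride * ow:stride] += t.transpose(0, 3, 1, 2)
            if padding:
                gx = gxp[:, :, padding:padding + h, padding:padding + wdt]
            else:
                gx = gxp
            x.accumulate(gx)

    return Tensor(y, parents=parents, backward=backward)


# ---------------------------------------------------------------------------
# Normalisation and activations
# ---------------------------------------------------------------------------

def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, *,
                running_mean: np.ndarray, running_var: np.ndarray,
                training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation; updates running stats in place."""
    xd = x.data
    if training:
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean[None, :, None, None]) * inv[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    if not _needs_grad(x, gamma, beta):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        if gamma.requires_grad or gamma._parents:
            gamma.accumulate((gy * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad or beta._parents:
            beta.accumulate(gy.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            g = gamma.data[None, :, None, None]
            if training:
                m = xd.shape[0] * xd.shape[2] * xd.shape[3]
                gxhat = gy * g
                s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (gxhat - s1 / m - xhat * s2 / m) * inv[None, :, None, None]
            else:
                gx = gy * g * inv[None, :, None, None]
            x.accumulate(gx)

    return Tensor(y, parents=[x, gamma, beta], backward=backward)


def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    neg = x.data < 0
    y = np.where(neg, slope * x.data, x.data)
    if not _needs_grad(x):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        x.accumulate(np.where(neg, slope * gy, gy))

    return Tensor(y, parents=[x], backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    if not _needs_grad(x):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        x.accumulate(gy * y * (1.0 - y))

    return Tensor(y, parents=[x], backward=backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    if not _needs_grad(x):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        dot = (gy * y).sum(axis=axis, keepdims=True)
        x.accumulate(y * (gy - dot))

    return Tensor(y, parents=[x], backward=backward)


# ---------------------------------------------------------------------------
# Structure ops
# ---------------------------------------------------------------------------

def concat_channels(tensors: Sequence[Tensor]) -> Tensor:
    y = np.concatenate([t.data for t in tensors], axis=1)
    if not _needs_grad(*tensors):
        return Tensor(y)
    sizes = [t.data.shape[1] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(gy: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents:
                t.accumulate(gy[:, lo:hi])

    return Tensor(y, parents=list(tensors), backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    y = a.data + b.data
    if not _needs_grad(a, b):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        if a.requires_grad or a._parents:
            a.accumulate(gy)
        if b.requires_grad or b._parents:
            b.accumulate(gy)

    return Tensor(y, parents=[a, b], backward=backward)


def scale(x: Tensor, s: float) -> Tensor:
    y = x.data * s
    if not _needs_grad(x):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        x.accumulate(gy * s)

    return Tensor(y, parents=[x], backward=backward)


_INTERP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (n_out x n_in), half-pixel
    centres (``align_corners=False``) with edge clamping — rows sum to 1."""
    key = (n_in, n_out)
    m = _INTERP_CACHE.get(key)
    if m is not None:
        return m
    m = np.zeros((n_out, n_in))
    ratio = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * ratio - 0.5
        i0 = int(np.floor(src))
        frac = src - i0
        i0c = min(max(i0, 0), n_in - 1)
        i1c = min(max(i0 + 1, 0), n_in - 1)
        m[o, i0c] += 1.0 - frac
        m[o, i1c] += frac
    _INTERP_CACHE[key] = m
    return m


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear x2 upsampling via separable interpolation matrices."""
    n, c, h, w = x.data.shape
    ah = _interp_matrix(h, 2 * h).astype(x.data.dtype)
    aw = _interp_matrix(w, 2 * w).astype(x.data.dtype)
    y = np.einsum("ij,ncjk,lk->ncil", ah, x.data, aw, optimize=True)
    if not _needs_grad(x):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        gx = np.einsum("ij,ncik,kl->ncjl", ah, gy, aw, optimize=True)
        x.accumulate(gx)

    return Tensor(y, parents=[x], backward=backward)


def linear(x: Tensor, w: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """Affine map: x (N, F_in) @ w.T (F_in, F_out) + b."""
    y = x.data @ w.data.T
    if b is not None:
        y = y + b.data
    parents = [x, w] + ([b] if b is not None else [])
    if not _needs_grad(*parents):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        if w.requires_grad or w._parents:
            w.accumulate(gy.T @ x.data)
        if b is not None and (b.requires_grad or b._parents):
            b.accumulate(gy.sum(axis=0))
        if x.requires_grad or x._parents:
            x.accumulate(gy @ w.data)

    return Tensor(y, parents=parents, backward=backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    n, c, h, w = x.data.shape
    y = x.data.mean(axis=(2, 3))
    if not _needs_grad(x):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        x.accumulate(np.broadcast_to(gy[:, :, None, None] / (h * w), x.data.shape).copy())

    return Tensor(y, parents=[x], backward=backward)
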