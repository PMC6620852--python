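"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine is a dynamic tape: every operation returns a :class:`Tensor`
holding its value, references to its parents and a closure that propagates
the upstream gradient.  ``Tensor.backward()`` topologically sorts the tape
and accumulates gradients, so a value consumed by several downstream ops
(e.g. an encoder feature feeding both a decoder and the next pooling layer)
receives the *sum* of the gradients from all consumers.

Only the operations the segmentation network needs are provided: 2-D
convolution, transposed convolution, 2x2 max-pooling, ReLU, sigmoid,
channel concatenation, spatial cropping and a weighted cross-entropy
reduction.  All arithmetic is float32 and runs on the CPU.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "conv2d",
    "conv_transpose2d",
    "maxpool2d",
    "relu",
    "sigmoid",
    "concat_channels",
    "crop2d",
    "weighted_bce_sum",
    "weighted_bce_logits_sum",
    "add",
    "add_n",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling tape recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, seed: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this tensor through the recorded tape."""
        if seed is None:
            if self.data.size != 1:
                raise ValueError("backward() without seed requires a scalar tensor")
            seed = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep graphs must not hit the recursion limit
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
        self._accumulate(np.asarray(seed, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad}, name={self.name!r})"


def _track(*tensors: Tensor) -> bool:
    return _GRAD_ENABLED and any(t.requires_grad for t in tensors)


# ---------------------------------------------------------------------------
# convolution


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N*Ho*Wo, C*kh*kw) patch matrix."""
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,Ho',Wo',kh,kw
    win = win[:, :, ::stride, ::stride]
    n, c, ho, wo = win.shape[:4]
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(col)


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor], stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW, weight (Cout,Cin,kh,kw)."""
    n, cin, h, wdt = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wdt + 2 * padding - kw) // stride + 1
    col = _im2col(xp, kh, kw, stride)
    wmat = w.data.reshape(cout, cin * kh * kw).T
    out = col @ wmat
    if b is not None:
        out += b.data
    y = out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    y = np.ascontiguousarray(y)
    if not _track(x, w) and (b is None or not _track(b)):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        gy2 = gy.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        if w.requires_grad:
            gw = (gy2.T @ col).reshape(cout, cin, kh, kw)
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(gy2.sum(axis=0))
        if x.requires_grad or x._parents:
            gcol = gy2 @ wmat.T
            gcol = gcol.reshape(n, ho, wo, cin, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            hp, wp = h + 2 * padding, wdt + 2 * padding
            gxp = np.zeros((n, cin, hp, wp), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += gcol[:, :, :, :, i, j]
            gx = gxp[:, :, padding : padding + h, padding : padding + wdt] if padding else gxp
            x._accumulate(gx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(y, requires_grad=True, parents=parents, backward=backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Optional[Tensor], stride: int = 2, padding: int = 1) -> Tensor:
    """Transposed convolution, weight (Cin,Cout,kh,kw).

    With the default kernel 4 / stride 2 / padding 1 the output is exactly
    twice the input size, the standard learnable x2 upsampling layer.
    """
    n, cin, h, wdt = x.data.shape
    cin_w, cout, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv_transpose2d channel mismatch: input {cin}, weight {cin_w}")
    ho = stride * (h - 1) + kh - 2 * padding
    wo = stride * (wdt - 1) + kw - 2 * padding
    full_h = stride * (h - 1) + kh
    full_w = stride * (wdt - 1) + kw
    t = np.tensordot(x.data, w.data, axes=([1], [0]))  # N,H,W,Cout,kh,kw
    yf = np.zeros((n, cout, full_h, full_w), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            yf[:, :, i : i + stride * h : stride, j : j + stride * wdt : stride] += t[..., i, j].transpose(0, 3, 1, 2)
    y = yf[:, :, padding : padding + ho, padding : padding + wo]
    y = np.ascontiguousarray(y)
    if b is not None:
        y += b.data[None, :, None, None]
    if not _track(x, w) and (b is None or not _track(b)):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        gyf = np.zeros((n, cout, full_h, full_w), dtype=np.float32)
        gyf[:, :, padding : padding + ho, padding : padding + wo] = gy
        if b is not None and b.requires_grad:
            b._accumulate(gy.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    sl = gyf[:, :, i : i + stride * h : stride, j : j + stride * wdt : stride]
                    gw[:, :, i, j] = np.tensordot(x.data, sl, axes=([0, 2, 3], [0, 2, 3]))
            w._accumulate(gw)
        if x.requires_grad or x._parents:
            gx = np.zeros((n, cin, h, wdt), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    sl = gyf[:, :, i : i + stride * h : stride, j : j + stride * wdt : stride]
                    gx += np.tensordot(sl, w.data[:, :, i, j], axes=([1], [1])).transpose(0, 3, 1, 2)
            x._accumulate(gx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(y, requires_grad=True, parents=parents, backward=backward)


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max-pooling with stride 2; spatial dims must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2d requires even spatial dims, got {h}x{w}")
    ho, wo = h // 2, w // 2
    v = x.data.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
    idx = v.argmax(axis=-1)
    y = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
    if not _track(x):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        gv = np.zeros((n, c, ho, wo, 4), dtype=np.float32)
        np.put_along_axis(gv, idx[..., None], gy[..., None], axis=-1)
        gx = gv.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accumulate(gx)

    return Tensor(y, requires_grad=True, parents=(x,), backward=backward)


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0.0)
    if not _track(x):
        return Tensor(y)
    mask = x.data > 0

    def backward(gy: np.ndarray) -> None:
        x._accumulate(gy * mask)

    return Tensor(y, requires_grad=True, parents=(x,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    y = expit(x.data).astype(np.float32)
    if not _track(x):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        x._accumulate(gy * y * (1.0 - y))

    return Tensor(y, requires_grad=True, parents=(x,), backward=backward)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    y = np.concatenate([t.data for t in tensors], axis=1)
    if not _track(*tensors):
        return Tensor(y)
    sizes = [t.data.shape[1] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(gy: np.ndarray) -> None:
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            t._accumulate(gy[:, a:b])

    return Tensor(y, requires_grad=True, parents=tuple(tensors), backward=backward)


def crop2d(x: Tensor, height: int, width: int) -> Tensor:
    """Center-crop the spatial dims to (height, width)."""
    n, c, h, w = x.data.shape
    if h < height or w < width:
        raise ValueError(f"cannot crop {h}x{w} to {height}x{width}")
    top = (h - height) // 2
    left = (w - width) // 2
    y = np.ascontiguousarray(x.data[:, :, top : top + height, left : left + width])
    if not _track(x):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        gx = np.zeros((n, c, h, w), dtype=np.float32)
        gx[:, :, top : top + height, left : left + width] = gy
        x._accumulate(gx)

    return Tensor(y, requires_grad=True, parents=(x,), backward=backward)


def add_n(tensors: list[Tensor]) -> Tensor:
    """Sum of same-shaped tensors (used to join the per-head losses).

    A graph with several loss heads must be backpropagated from a single
    root: per-head ``backward()`` calls would re-propagate the gradient
    already accumulated on shared encoder nodes.
    """
    y = tensors[0].data.copy()
    for t in tensors[1:]:
        y += t.data
    if not _track(*tensors):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        for t in tensors:
            t._accumulate(gy)

    return Tensor(y, requires_grad=True, parents=tuple(tensors), backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    y = a.data + b.data
    if not _track(a, b):
        return Tensor(y)

    def backward(gy: np.ndarray) -> None:
        if a.requires_grad or a._parents:
            a._accumulate(gy)
        if b.requires_grad or b._parents:
            b._accumulate(gy)

    return Tensor(y, requires_grad=True, parents=(a, b), backward=backward)


def weighted_bce_sum(p: Tensor, y: np.ndarray, weights: np.ndarray) -> Tensor:
    """Sum over pixels of -weights * [y log p + (1-y) log(1-p)].

    ``weights`` already folds in any gating (zero weight = pixel excluded
    from both the value and the gradient).  Probabilities are clamped to
    [1e-7, 1 - 1e-7] before the logarithm.
    """
    from .objective import bce_value_and_grad  # single source of truth

    val, dp = bce_value_and_grad(p.data, y, weights)
    out = np.float32(val)
    if not _track(p):
        return Tensor(out)

    def backward(gy: np.ndarray) -> None:
        p._accumulate(float(np.asarray(gy).reshape(-1)[0]) * dp)

    return Tensor(out, requires_grad=True, parents=(p,), backward=backward)


def weighted_bce_logits_sum(z: Tensor, y: np.ndarray, weights: np.ndarray) -> Tensor:
    """Weighted cross-entropy evaluated from logits.

    Identical value to ``weighted_bce_sum(sigmoid(z), ...)`` but computed
    in logit space: log P = -softplus(-z), log(1-P) = -softplus(z), and
    the gradient is exactly w * (sigmoid(z) - y).  This keeps gradients
    alive where the sigmoid saturates, which the probability-space form
    cannot (its clamp flattens the gradient at saturated pixels).
    """
    zd = z.data
    # softplus(x) = log(1 + e^x), computed stably
    sp_pos = np.logaddexp(0.0, zd)  # softplus(z)
    sp_neg = sp_pos - zd  # softplus(-z)
    w = np.asarray(weights, dtype=np.float32)
    yy = np.asarray(y, dtype=np.float32)
    val = np.sum(w * (yy * sp_neg + (1.0 - yy) * sp_pos), dtype=np.float64)
    out = np.float32(val)
    if not _track(z):
        return Tensor(out)
    p = expit(zd)

    def backward(gy: np.ndarray) -> None:
        z._accumulate(float(np.asarray(gy).reshape(-1)[0]) * (w * (p - yy)))

    return Tensor(out, requires_grad=True, parents=(z,), backward=backward)
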