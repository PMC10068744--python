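"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for a small volumetric segmentation network: 3D
"same"-padded convolution, stride-2 transposed convolution, average
pooling, channel/spatial reductions, dense layers, pointwise
nonlinearities, and a numerically stable binary cross-entropy on logits.
Feature maps are (C, D, H, W) single-sample arrays in float32; gradients
are accumulated by a topological backward sweep over the recorded tape.

Convolutions use a shift-and-matmul scheme: for each of the k^3 kernel
offsets, a channel-mixing matrix multiplies a shifted view of the padded
input, so the heavy lifting stays inside BLAS with O(C * N) memory.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor", "no_grad", "is_grad_enabled",
    "add", "mul", "relu", "sigmoid", "concat",
    "conv3d", "tconv2", "avg_pool",
    "global_avg_pool", "global_max_pool", "channel_mean", "channel_max",
    "linear", "bce_with_logits",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference mode)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _acc(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad:
        t.grad = g if t.grad is None else t.grad + g


def _make(data: np.ndarray, parents: Sequence[Tensor], backward: Callable) -> Tensor:
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g):
        _acc(a, _unbroadcast(g, a.data.shape))
        _acc(b, _unbroadcast(g, b.data.shape))

    return _make(out, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def backward(g):
        _acc(a, _unbroadcast(g * b.data, a.data.shape))
        _acc(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0)
    if not (_GRAD_ENABLED and x.requires_grad):
        return Tensor(out)
    mask = x.data > 0

    def backward(g):
        _acc(x, g * mask)

    return _make(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    from scipy.special import expit

    s = expit(x.data)

    def backward(g):
        _acc(x, g * s * (1.0 - s))

    return _make(s, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        start = 0
        for t, s in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + s)
            _acc(t, g[tuple(sl)])
            start += s

    return _make(out, tuple(tensors), backward)


def _conv3d_im2col(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Training path: one im2col matrix + a single BLAS matmul each way."""
    cout, cin, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    p = k // 2
    d, h, wd = x.data.shape[1:]
    n = d * h * wd
    kk = k * k * k
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p))) if p else x.data
    offs = [(dz, dy, dx) for dz in range(k) for dy in range(k) for dx in range(k)]
    col = np.empty((kk, cin, n), dtype=np.float32)
    for oi, (dz, dy, dx) in enumerate(offs):
        col[oi] = xp[:, dz:dz + d, dy:dy + h, dx:dx + wd].reshape(cin, n)
    colf = col.reshape(kk * cin, n)
    # weight laid out (cout, offset, cin) to match the column ordering
    wflat = np.ascontiguousarray(
        w.data.reshape(cout, cin, kk).transpose(0, 2, 1)
    ).reshape(cout, kk * cin)
    out = (wflat @ colf).reshape(cout, d, h, wd) + b.data[:, None, None, None]

    def backward(g):
        g2 = g.reshape(cout, n)
        _acc(b, g.sum(axis=(1, 2, 3)))
        if w.requires_grad:
            gw = (g2 @ colf.T).reshape(cout, kk, cin).transpose(0, 2, 1)
            _acc(w, np.ascontiguousarray(gw).reshape(w.data.shape))
        if x.requires_grad:
            gcol = (wflat.T @ g2).reshape(kk, cin, n)
            gxp = np.zeros_like(xp)
            for oi, (dz, dy, dx) in enumerate(offs):
                gxp[:, dz:dz + d, dy:dy + h, dx:dx + wd] += gcol[oi].reshape(cin, d, h, wd)
            _acc(x, gxp[:, p:p + d, p:p + h, p:p + wd] if p else gxp)

    return _make(out, (x, w, b), backward)


def _conv3d_shift(x: Tensor, w: Tensor, b: Tensor) -> np.ndarray:
    """Inference path: shifted-view matmuls, O(C*N) extra memory."""
    cout, cin, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    p = k // 2
    d, h, wd = x.data.shape[1:]
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p))) if p else x.data
    wmat = w.data.reshape(cout, cin, k * k * k)
    out2 = np.zeros((cout, d * h * wd), dtype=np.float32)
    oi = 0
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                seg = xp[:, dz:dz + d, dy:dy + h, dx:dx + wd].reshape(cin, -1)
                out2 += wmat[:, :, oi] @ seg
                oi += 1
    return out2.reshape(cout, d, h, wd) + b.data[:, None, None, None]


def _conv3d_fft(x: Tensor, w: Tensor, b: Tensor) -> np.ndarray:
    """Inference path for large kernels (the 7^3 spatial-attention conv)."""
    from scipy.signal import fftconvolve

    cout, cin = w.data.shape[0], w.data.shape[1]
    out = np.empty((cout,) + x.data.shape[1:], dtype=np.float32)
    for co in range(cout):
        acc = None
        for ci in range(cin):
            kern = w.data[co, ci, ::-1, ::-1, ::-1]  # correlation via flipped kernel
            term = fftconvolve(x.data[ci], kern, mode="same")
            acc = term if acc is None else acc + term
        out[co] = acc + b.data[co]
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """k^3 'same' (zero-padded) convolution; x (Cin,D,H,W), w (Cout,Cin,k,k,k)."""
    cin, k = w.data.shape[1], w.data.shape[2]
    if x.data.shape[0] != cin:
        raise ValueError(f"conv3d: input has {x.data.shape[0]} channels, weight expects {cin}")
    grad_needed = _GRAD_ENABLED and (x.requires_grad or w.requires_grad or b.requires_grad)
    if grad_needed:
        return _conv3d_im2col(x, w, b)
    if k >= 5 and x.data[0].size >= 1 << 15:
        return Tensor(_conv3d_fft(x, w, b))
    return Tensor(_conv3d_shift(x, w, b))


def tconv2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-2 kernel-2 transposed convolution (x2 upsampling); w (Cin,Cout,2,2,2)."""
    cin, cout = w.data.shape[0], w.data.shape[1]
    if x.data.shape[0] != cin:
        raise ValueError(f"tconv2: input has {x.data.shape[0]} channels, weight expects {cin}")
    d, h, wd = x.data.shape[1:]
    out = np.empty((cout, 2 * d, 2 * h, 2 * wd), dtype=np.float32)
    corners = [(a, bb, c) for a in range(2) for bb in range(2) for c in range(2)]
    for a, bb, c in corners:
        wc = w.data[:, :, a, bb, c]  # (Cin, Cout)
        out[:, a::2, bb::2, c::2] = np.tensordot(wc.T, x.data, axes=([1], [0]))
    out += b.data[:, None, None, None]

    def backward(g):
        _acc(b, g.sum(axis=(1, 2, 3)))
        gx = np.zeros_like(x.data) if x.requires_grad else None
        gw = np.zeros_like(w.data) if w.requires_grad else None
        for a, bb, c in corners:
            gc = g[:, a::2, bb::2, c::2]  # (Cout, d, h, wd)
            wc = w.data[:, :, a, bb, c]
            if gx is not None:
                gx += np.tensordot(wc, gc, axes=([1], [0]))
            if gw is not None:
                gw[:, :, a, bb, c] = np.tensordot(x.data, gc, axes=([1, 2, 3], [1, 2, 3]))
        if gx is not None:
            _acc(x, gx)
        if gw is not None:
            _acc(w, gw)

    return _make(out, (x, w, b), backward)


def avg_pool(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping mean pooling by an integer factor along each spatial axis."""
    if factor == 1:
        return x
    c, d, h, wd = x.data.shape
    if d % factor or h % factor or wd % factor:
        raise ValueError(f"avg_pool: spatial shape {(d, h, wd)} not divisible by {factor}")
    f = factor
    out = x.data.reshape(c, d // f, f, h // f, f, wd // f, f).mean(axis=(2, 4, 6))

    def backward(g):
        gi = np.broadcast_to(
            g[:, :, None, :, None, :, None] / (f ** 3),
            (c, d // f, f, h // f, f, wd // f, f),
        ).reshape(c, d, h, wd)
        _acc(x, np.ascontiguousarray(gi))

    return _make(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    c = x.data.shape[0]
    n = x.data[0].size
    out = x.data.reshape(c, -1).mean(axis=1)

    def backward(g):
        _acc(x, np.broadcast_to((g / n)[:, None, None, None], x.data.shape).copy())

    return _make(out, (x,), backward)


def global_max_pool(x: Tensor) -> Tensor:
    c = x.data.shape[0]
    flat = x.data.reshape(c, -1)
    idx = flat.argmax(axis=1)
    out = flat[np.arange(c), idx]

    def backward(g):
        gi = np.zeros_like(flat)
        gi[np.arange(c), idx] = g
        _acc(x, gi.reshape(x.data.shape))

    return _make(out, (x,), backward)


def channel_mean(x: Tensor) -> Tensor:
    c = x.data.shape[0]
    out = x.data.mean(axis=0, keepdims=True)

    def backward(g):
        _acc(x, np.broadcast_to(g / c, x.data.shape).copy())

    return _make(out, (x,), backward)


def channel_max(x: Tensor) -> Tensor:
    if not (_GRAD_ENABLED and x.requires_grad):
        return Tensor(x.data.max(axis=0, keepdims=True))
    idx = x.data.argmax(axis=0)
    out = np.take_along_axis(x.data, idx[None], axis=0)

    def backward(g):
        gi = np.zeros_like(x.data)
        np.put_along_axis(gi, idx[None], g, axis=0)
        _acc(x, gi)

    return _make(out, (x,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Dense layer on a vector: w (out, in) @ x (in,) + b (out,)."""
    out = w.data @ x.data + b.data

    def backward(g):
        _acc(b, g)
        _acc(w, np.outer(g, x.data))
        _acc(x, w.data.T @ g)

    return _make(out, (x, w, b), backward)


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from logits (numerically stable)."""
    z = logits.data
    t = np.asarray(target, dtype=np.float32)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out = np.array(loss.mean(), dtype=np.float32)
    n = z.size

    def backward(g):
        from scipy.special import expit

        _acc(logits, g * (expit(z) - t) / n)

    return _make(out, (logits,), backward)
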