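"""Compact reverse-mode automatic differentiation on numpy arrays.

Provides exactly the primitives the reconstruction network and its SSIM loss
need: broadcasted arithmetic, leaky ReLU, sigmoid, 2-D convolution (stride 1,
arbitrary dilation, implemented as im2col + GEMM), pixel shuffle, channel
concatenation, spatial/global means, and reshape.  Gradients are accumulated
by topological-order traversal of the operation tape; every primitive's
backward rule is verified against central finite differences in the test
suite.

A graph is only recorded when some input has ``requires_grad``; inference is
allocation-light.  dtype follows the inputs (float32 for training, float64
for gradient checks).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "sub",
    "mul",
    "div",
    "leaky_relu",
    "sigmoid",
    "conv2d",
    "pixel_shuffle",
    "concat",
    "spatial_mean",
    "mean",
    "reshape",
]


class Tensor:
    """A numpy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-sweep the tape rooted at this tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, self.data.dtype)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _tracked(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _make(data: np.ndarray, parents: tuple, backward) -> Tensor:
    out = Tensor(data)
    if _tracked(*parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# Elementwise primitives
# ---------------------------------------------------------------------------

def _is_num(x) -> bool:
    return isinstance(x, (int, float, np.integer, np.floating))


def _scalar(s, like: np.ndarray):
    return np.asarray(s, dtype=like.dtype)  # 0-d, dtype-preserving under NEP 50


def add(a, b) -> Tensor:
    if _is_num(a) or _is_num(b):
        t = a if isinstance(a, Tensor) else b
        s = _scalar(b if t is a else a, t.data)

        def backward(g):
            t._accumulate(g)

        return _make(t.data + s, (t,), backward)
    a, b = _t(a), _t(b)

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward)


def sub(a, b) -> Tensor:
    if _is_num(b):
        return add(a, -b)
    if _is_num(a):
        t = b
        s = _scalar(a, t.data)

        def backward(g):
            t._accumulate(-g)

        return _make(s - t.data, (t,), backward)
    a, b = _t(a), _t(b)

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(-g, b.data.shape))

    return _make(a.data - b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    if _is_num(a) or _is_num(b):
        t = a if isinstance(a, Tensor) else b
        s = _scalar(b if t is a else a, t.data)

        def backward(g):
            t._accumulate(g * s)

        return _make(t.data * s, (t,), backward)
    a, b = _t(a), _t(b)

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward)


def div(a, b) -> Tensor:
    if _is_num(b):
        return mul(a, 1.0 / b)
    if _is_num(a):
        t = b
        s = _scalar(a, t.data)

        def backward(g):
            t._accumulate(-g * s / (t.data * t.data))

        return _make(s / t.data, (t,), backward)
    a, b = _t(a), _t(b)

    def backward(g):
        a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _make(a.data / b.data, (a, b), backward)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    pos = x.data > 0

    def backward(g):
        x._accumulate(g * np.where(pos, 1.0, slope))

    return _make(np.where(pos, x.data, slope * x.data), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable two-sided form
    y = np.empty_like(x.data)
    p = x.data >= 0
    y[p] = 1.0 / (1.0 + np.exp(-x.data[p]))
    e = np.exp(x.data[~p])
    y[~p] = e / (1.0 + e)

    def backward(g):
        x._accumulate(g * y * (1.0 - y))

    return _make(y, (x,), backward)


# ---------------------------------------------------------------------------
# Reductions / shape ops
# ---------------------------------------------------------------------------

def mean(x: Tensor) -> Tensor:
    n = x.data.size

    def backward(g):
        x._accumulate(np.full_like(x.data, g / n))

    return _make(np.asarray(x.data.mean(), dtype=x.data.dtype), (x,), backward)


def spatial_mean(x: Tensor) -> Tensor:
    """Global average pool over the last two axes, keepdims (B, C, 1, 1)."""
    h, w = x.data.shape[-2:]

    def backward(g):
        x._accumulate(np.broadcast_to(g / (h * w), x.data.shape).copy())

    return _make(x.data.mean(axis=(-2, -1), keepdims=True), (x,), backward)


def reshape(x: Tensor, shape: tuple) -> Tensor:
    orig = x.data.shape

    def backward(g):
        x._accumulate(g.reshape(orig))

    return _make(x.data.reshape(shape), (x,), backward)


def concat(tensors: list, axis: int = 1) -> Tensor:
    tensors = [_t(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return _make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def pixel_shuffle(x: Tensor, factor: int) -> Tensor:
    """(B, C*r^2, H, W) -> (B, C, H*r, W*r) channel-to-space rearrangement."""
    b, c, h, w = x.data.shape
    r = factor
    if c % (r * r):
        raise ValueError("channels must be divisible by factor**2")
    co = c // (r * r)
    y = (
        x.data.reshape(b, co, r, r, h, w)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(b, co, h * r, w * r)
    )

    def backward(g):
        gx = (
            g.reshape(b, co, h, r, w, r)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(b, c, h, w)
        )
        x._accumulate(gx)

    return _make(y, (x,), backward)


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, pad: int, dil: int):
    b, c, h, w = x.shape
    hout = h + 2 * pad - dil * (kh - 1)
    wout = w + 2 * pad - dil * (kw - 1)
    if hout < 1 or wout < 1:
        raise ValueError("kernel (with dilation) exceeds padded input size")
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    s0, s1, s2, s3 = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp,
        shape=(b, c, kh, kw, hout, wout),
        strides=(s0, s1, s2 * dil, s3 * dil, s2, s3),
        writeable=False,
    )
    return win.reshape(b, c * kh * kw, hout * wout), hout, wout


def _col2im(
    gcols: np.ndarray, xshape: tuple, kh: int, kw: int, pad: int, dil: int,
    hout: int, wout: int,
) -> np.ndarray:
    b, c, h, w = xshape
    gxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=gcols.dtype)
    g6 = gcols.reshape(b, c, kh, kw, hout, wout)
    for i in range(kh):
        for j in range(kw):
            gxp[:, :, i * dil : i * dil + hout, j * dil : j * dil + wout] += g6[
                :, :, i, j
            ]
    return gxp[:, :, pad : pad + h, pad : pad + w] if pad else gxp


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    padding: int = 0,
    dilation: int = 1,
) -> Tensor:
    """2-D convolution (cross-correlation), stride 1.

    x: (B, Cin, H, W); weight: (Cout, Cin, kh, kw); bias: (Cout,) or None.
    """
    cout, cin, kh, kw = weight.data.shape
    if x.data.shape[1] != cin:
        raise ValueError(
            f"input has {x.data.shape[1]} channels, weight expects {cin}"
        )
    cols, hout, wout = _im2col(x.data, kh, kw, padding, dilation)
    w2 = weight.data.reshape(cout, cin * kh * kw)
    y = np.matmul(w2, cols).reshape(x.data.shape[0], cout, hout, wout)
    if bias is not None:
        y += bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        b = x.data.shape[0]
        g2 = g.reshape(b, cout, hout * wout)
        if weight.requires_grad or weight._parents:
            gw = np.einsum("bol,bkl->ok", g2, cols, optimize=True)
            weight._accumulate(gw.reshape(weight.data.shape))
        if bias is not None and (bias.requires_grad or bias._parents):
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gcols = np.matmul(w2.T, g2)
            x._accumulate(
                _col2im(gcols, x.data.shape, kh, kw, padding, dilation, hout, wout)
            )

    return _make(y, parents, backward)
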