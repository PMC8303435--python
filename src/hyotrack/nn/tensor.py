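"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine follows the classic tape-free design: every operation returns a new
:class:`Tensor` holding a closure that propagates the output gradient to the
operation's parents.  ``backward()`` runs a topological sort from the loss and
invokes the closures in reverse order.  All arrays are float32; shapes follow
NCHW for image tensors.

Only the operations needed by the segmentation network are provided.  Each one
is gradient-checked against central finite differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Optional, Sequence, Tuple

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: Tuple["Tensor", ...] = ()
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}, name={self.name!r})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __neg__(self):
        return mul_scalar(self, -1.0)

    def __sub__(self, other):
        return add(self, mul_scalar(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul_scalar(self, -1.0))

    def __mul__(self, other):
        if np.isscalar(other):
            return mul_scalar(self, float(other))
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if np.isscalar(other):
            return mul_scalar(self, 1.0 / float(other))
        return mul(self, pow_scalar(_wrap(other), -1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------- primitives
def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def mul_scalar(a: Tensor, s: float) -> Tensor:
    data = a.data * s

    def backward(g):
        a._accumulate(g * s)

    return _make(data, (a,), backward)


def pow_scalar(a: Tensor, p: float) -> Tensor:
    data = a.data ** p

    def backward(g):
        a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(data, (a,), backward)


def texp(a: Tensor) -> Tensor:
    data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * data)

    return _make(data, (a,), backward)


def tlog(a: Tensor) -> Tensor:
    data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    data = np.maximum(a.data, 0.0)

    def backward(g):
        a._accumulate(g * (a.data > 0.0))

    return _make(data, (a,), backward)


def clamp_min(a: Tensor, lo: float) -> Tensor:
    """max(a, lo); gradient passes only where a > lo."""
    data = np.maximum(a.data, lo)

    def backward(g):
        a._accumulate(g * (a.data > lo))

    return _make(data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accumulate(_unbroadcast(ga, a.shape))
        b._accumulate(_unbroadcast(gb, b.shape))

    return _make(data, (a, b), backward)


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).astype(np.float32))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).astype(np.float32))

    return _make(data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else np.prod([a.shape[ax] for ax in np.atleast_1d(axis)])
    return mul_scalar(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a: Tensor, shape) -> Tensor:
    data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.shape))

    return _make(data, (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        a._accumulate(g.transpose(inv))

    return _make(data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _make(data, tensors, backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        a._accumulate(s * (g - dot))

    return _make(s, (a,), backward)


def log_softmax(a: Tensor, axis: int = 1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    sm = np.exp(out)

    def backward(g):
        a._accumulate(g - sm * g.sum(axis=axis, keepdims=True))

    return _make(out, (a,), backward)


# -------------------------------------------------------------- convolution
def _im2col(x: np.ndarray, kh: int, kw: int, pad: int):
    """(N,C,H,W) -> contiguous (N, C*kh*kw, OH*OW) for stride-1 windows."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh, ow = h + 2 * pad - kh + 1, w + 2 * pad - kw + 1
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + oh, j : j + ow]
    return cols.reshape(n, c * kh * kw, oh * ow), (oh, ow)


def _col2im(cols: np.ndarray, xshape, kh: int, kw: int, pad: int) -> np.ndarray:
    n, c, h, w = xshape
    oh, ow = h + 2 * pad - kh + 1, w + 2 * pad - kw + 1
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + oh, j : j + ow] += cols[:, :, i, j]
    if pad:
        xp = xp[:, :, pad:-pad, pad:-pad]
    return xp


def _conv1x1(x: Tensor, w: Tensor, b: Optional[Tensor]) -> Tensor:
    n, c, h, w_ = x.shape
    cout = w.shape[0]
    wmat = w.data.reshape(cout, c)
    xm = x.data.reshape(n, c, h * w_)
    out = wmat @ xm
    if b is not None:
        out += b.data[:, None]
    out = out.reshape(n, cout, h, w_)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gm = g.reshape(n, cout, h * w_)
        gw = np.einsum("nij,nkj->ik", gm, xm, optimize=True)
        w._accumulate(gw.reshape(w.shape))
        x._accumulate((wmat.T @ gm).reshape(x.shape))
        if b is not None:
            b._accumulate(gm.sum(axis=(0, 2)))

    return _make(out, parents, backward)


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None, padding: int = 0) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), NCHW / (Cout,Cin,kh,kw)."""
    cout, cin, kh, kw = w.shape
    if kh == 1 and kw == 1 and padding == 0:
        return _conv1x1(x, w, b)
    n = x.shape[0]
    cols, (oh, ow) = _im2col(x.data, kh, kw, padding)
    wmat = w.data.reshape(cout, -1)
    out = wmat @ cols  # (N, Cout, OH*OW)
    if b is not None:
        out += b.data[:, None]
    out = out.reshape(n, cout, oh, ow)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.reshape(n, cout, oh * ow)
        gw = np.einsum("nij,nkj->ik", gmat, cols, optimize=True)
        w._accumulate(gw.reshape(w.shape))
        gcols = np.matmul(wmat.T, gmat)  # (N, C*kh*kw, OHW)
        x._accumulate(_col2im(gcols, x.shape, kh, kw, padding))
        if b is not None:
            b._accumulate(gmat.sum(axis=(0, 2)))

    return _make(out, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 requires even spatial size, got {h}x{w}")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    blocks = blocks.reshape(n, c, h // 2, w // 2, 4)
    idx = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gb = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
        gb = gb.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gb.reshape(n, c, h, w))

    return _make(out, (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return _make(out, (x,), backward)


def relative_logits(q: Tensor, rh: Tensor, rw: Tensor, h: int, w: int) -> Tensor:
    """Content-to-position attention logits with learned relative encodings.

    q: (B, HW, d); rh: (2h-1, d); rw: (2w-1, d).  Output (B, HW, HW) where
    entry (i, j) = q_i . (rh[dy(i,j)+h-1] + rw[dx(i,j)+w-1]).
    """
    ys, xs = np.divmod(np.arange(h * w), w)
    dy = ys[:, None] - ys[None, :] + h - 1  # (HW, HW)
    dx = xs[:, None] - xs[None, :] + w - 1
    r = rh.data[dy] + rw.data[dx]  # (HW, HW, d)
    out = np.einsum("bid,ijd->bij", q.data, r, optimize=True)

    def backward(g):
        q._accumulate(np.einsum("bij,ijd->bid", g, r, optimize=True))
        gr = np.einsum("bij,bid->ijd", g, q.data, optimize=True)
        grh = np.zeros_like(rh.data)
        grw = np.zeros_like(rw.data)
        np.add.at(grh, dy, gr)
        np.add.at(grw, dx, gr)
        rh._accumulate(grh)
        rw._accumulate(grw)

    return _make(out, (q, rh, rw), backward)
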