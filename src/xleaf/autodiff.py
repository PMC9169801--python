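"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine exists to support two requirements that rule out plain hand-coded
backprop:

* the right-reasons penalty differentiates the *input gradient* of the
  network with respect to the model parameters (double backpropagation), and
* Grad-CAM needs gradients of a single class score with respect to an
  intermediate feature map.

Every primitive's backward rule is itself expressed in :class:`Tensor`
operations, so gradients are ordinary graph nodes and can be differentiated
again.  Convolution and pooling are built from ``gather``/``scatter_add`` and
``matmul``, which keeps the rule set small and second-order-exact.

All data is float32.  The engine is deterministic: identical inputs produce
bit-identical outputs on a fixed machine.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "grad",
    "add", "sub", "mul", "div", "neg", "pow_const", "exp", "log", "relu",
    "matmul", "reshape", "transpose", "tsum", "tmean", "tmax",
    "broadcast_to", "gather", "scatter_add", "pad2d", "crop2d",
    "conv2d", "maxpool2d", "global_avg_pool", "linear",
    "softmax", "log_softmax", "cross_entropy",
]


class Tensor:
    """A NumPy array plus the graph edges needed for reverse-mode AD."""

    __slots__ = ("data", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        arr = np.asarray(data)
        if arr.dtype != np.float32:
            arr = arr.astype(np.float32)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        # parents: tuple of (Tensor, vjp) where vjp maps the output cotangent
        # (a Tensor) to the parent's cotangent (a Tensor).
        self._parents = parents

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # operator sugar
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __neg__(self):
        return neg(self)

    def __pow__(self, k):
        return pow_const(self, float(k))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _make(data, parents) -> Tensor:
    req = any(p.requires_grad for p, _ in parents)
    return Tensor(data, requires_grad=req, parents=tuple(parents) if req else ())


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a cotangent back to ``shape`` after NumPy broadcasting."""
    if g.shape == shape:
        return g
    # sum extra leading axes
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    # sum axes that were broadcast from 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


# -- elementwise ----------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.data + b.data, [
        (a, lambda g: _unbroadcast(g, a.shape)),
        (b, lambda g: _unbroadcast(g, b.shape)),
    ])


def sub(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.data - b.data, [
        (a, lambda g: _unbroadcast(g, a.shape)),
        (b, lambda g: _unbroadcast(neg(g), b.shape)),
    ])


def neg(a: Tensor) -> Tensor:
    return _make(-a.data, [(a, lambda g: neg(g))])


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.data * b.data, [
        (a, lambda g: _unbroadcast(mul(g, b), a.shape)),
        (b, lambda g: _unbroadcast(mul(g, a), b.shape)),
    ])


def div(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.data / b.data, [
        (a, lambda g: _unbroadcast(div(g, b), a.shape)),
        (b, lambda g: _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape)),
    ])


def pow_const(a: Tensor, k: float) -> Tensor:
    out = a.data ** k
    return _make(out, [(a, lambda g: mul(g, mul(Tensor(np.float32(k)), pow_const(a, k - 1.0))))])


def exp(a: Tensor) -> Tensor:
    out_t = Tensor(np.exp(a.data), requires_grad=a.requires_grad)
    if a.requires_grad:
        out_t._parents = ((a, lambda g: mul(g, out_t)),)
    return out_t


def log(a: Tensor) -> Tensor:
    return _make(np.log(a.data), [(a, lambda g: div(g, a))])


def relu(a: Tensor) -> Tensor:
    mask = (a.data > 0).astype(np.float32)
    mask_t = Tensor(mask)
    return _make(a.data * mask, [(a, lambda g: mul(g, mask_t))])


# -- shape ops ------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    old = a.shape
    return _make(a.data.reshape(shape), [(a, lambda g: reshape(g, old))])


def transpose(a: Tensor, axes: Sequence[int]) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _make(a.data.transpose(axes), [(a, lambda g: transpose(g, inv))])


def broadcast_to(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    old = a.shape
    return _make(np.broadcast_to(a.data, shape).copy(),
                 [(a, lambda g: _unbroadcast(g, old))])


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis,)
    else:
        axes = tuple(axis)
    axes = tuple(ax % a.ndim for ax in axes)
    old = a.shape

    def backward(g: Tensor) -> Tensor:
        if not keepdims:
            kshape = tuple(1 if i in axes else s for i, s in enumerate(old))
            g = reshape(g, kshape)
        return broadcast_to(g, old)

    return _make(a.data.sum(axis=axes, keepdims=keepdims), [(a, backward)])


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(np.float32(1.0 / n)))


def tmax(a: Tensor, axis: int) -> Tensor:
    """Max-reduce along one axis; the cotangent routes to the first argmax."""
    axis = axis % a.ndim
    out = a.data.max(axis=axis)
    idx = a.data.argmax(axis=axis)
    onehot = np.zeros(a.shape, dtype=np.float32)
    np.put_along_axis(onehot, np.expand_dims(idx, axis), 1.0, axis=axis)
    onehot_t = Tensor(onehot)

    def backward(g: Tensor) -> Tensor:
        kshape = tuple(1 if i == axis else s for i, s in enumerate(a.shape))
        return mul(broadcast_to(reshape(g, kshape), a.shape), onehot_t)

    return _make(out, [(a, backward)])


# -- linear algebra -------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    def back_a(g: Tensor) -> Tensor:
        bt = transpose(b, tuple(range(b.ndim - 2)) + (b.ndim - 1, b.ndim - 2))
        ga = matmul(g, bt)
        if ga.ndim > a.ndim:
            ga = tsum(ga, axis=tuple(range(ga.ndim - a.ndim)))
        return ga

    def back_b(g: Tensor) -> Tensor:
        at = transpose(a, tuple(range(a.ndim - 2)) + (a.ndim - 1, a.ndim - 2))
        gb = matmul(at, g)
        if gb.ndim > b.ndim:
            gb = tsum(gb, axis=tuple(range(gb.ndim - b.ndim)))
        return gb

    return _make(np.matmul(a.data, b.data), [(a, back_a), (b, back_b)])


# -- gather / scatter (the basis for conv and pooling) --------------------

def gather(a: Tensor, idx: np.ndarray) -> Tensor:
    """Take flat indices ``idx`` along the last axis of a 2-D tensor (B, S)."""
    idx = np.ascontiguousarray(idx.ravel())
    size = a.shape[-1]
    out = np.take(a.data, idx, axis=-1)
    return _make(out, [(a, lambda g: scatter_add(g, idx, size))])


def scatter_add(g: Tensor, idx: np.ndarray, size: int) -> Tensor:
    """Adjoint of :func:`gather`: sum ``g[..., j]`` into slot ``idx[j]``."""
    idx = np.ascontiguousarray(idx.ravel())
    lead = g.shape[:-1]
    nb = int(np.prod(lead)) if lead else 1
    flat = g.data.reshape(nb, -1)
    offs = (np.arange(nb, dtype=np.int64) * size)[:, None]
    full = (offs + idx[None, :]).ravel()
    acc = np.bincount(full, weights=flat.ravel().astype(np.float64),
                      minlength=nb * size).astype(np.float32)
    out = acc.reshape(lead + (size,))
    return _make(out, [(g, lambda gg: gather(gg, idx))])


def pad2d(a: Tensor, p: int) -> Tensor:
    """Zero-pad the two trailing axes of an NCHW tensor."""
    if p == 0:
        return a
    width = [(0, 0)] * (a.ndim - 2) + [(p, p), (p, p)]
    return _make(np.pad(a.data, width), [(a, lambda g: crop2d(g, p))])


def crop2d(a: Tensor, p: int) -> Tensor:
    if p == 0:
        return a
    sl = (Ellipsis, slice(p, a.shape[-2] - p), slice(p, a.shape[-1] - p))
    return _make(a.data[sl], [(a, lambda g: pad2d(g, p))])


@lru_cache(maxsize=64)
def _conv_indices(C: int, Hp: int, Wp: int, k: int, s: int):
    """Flat im2col indices into a (C*Hp*Wp) image, shape (OH*OW, C*k*k)."""
    OH = (Hp - k) // s + 1
    OW = (Wp - k) // s + 1
    oh = np.arange(OH)[:, None, None, None, None]
    ow = np.arange(OW)[None, :, None, None, None]
    c = np.arange(C)[None, None, :, None, None]
    ki = np.arange(k)[None, None, None, :, None]
    kj = np.arange(k)[None, None, None, None, :]
    idx = c * (Hp * Wp) + (oh * s + ki) * Wp + (ow * s + kj)
    return idx.reshape(OH * OW, C * k * k), OH, OW


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) on NCHW input via im2col."""
    B, C, H, W = x.shape
    F, Cw, k, k2 = w.shape
    if Cw != C or k != k2:
        raise ValueError(f"weight shape {w.shape} incompatible with input {x.shape}")
    xp = pad2d(x, padding)
    Hp, Wp = H + 2 * padding, W + 2 * padding
    idx, OH, OW = _conv_indices(C, Hp, Wp, k, stride)
    cols = reshape(gather(reshape(xp, (B, C * Hp * Wp)), idx),
                   (B, OH * OW, C * k * k))
    wf = transpose(reshape(w, (F, C * k * k)), (1, 0))
    y = matmul(cols, wf)  # (B, OH*OW, F)
    y = transpose(reshape(y, (B, OH, OW, F)), (0, 3, 1, 2))
    if b is not None:
        y = add(y, reshape(b, (1, F, 1, 1)))
    return y


def maxpool2d(x: Tensor, k: int, stride: int) -> Tensor:
    B, C, H, W = x.shape
    idx, OH, OW = _conv_indices(1, H, W, k, stride)
    cols = reshape(gather(reshape(x, (B * C, H * W)), idx),
                   (B * C, OH * OW, k * k))
    return reshape(tmax(cols, axis=-1), (B, C, OH, OW))


def global_avg_pool(x: Tensor) -> Tensor:
    return tmean(x, axis=(-2, -1))


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x (B, D) @ w (D, F) + b (F,)."""
    return add(matmul(x, w), b)


# -- softmax / loss -------------------------------------------------------

def log_softmax(z: Tensor) -> Tensor:
    m = Tensor(z.data.max(axis=-1, keepdims=True))  # constant shift
    zs = sub(z, m)
    lse = log(tsum(exp(zs), axis=-1, keepdims=True))
    return sub(zs, lse)


def softmax(z: Tensor) -> Tensor:
    return exp(log_softmax(z))


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood over the batch; labels are int indices."""
    n = logits.shape[-1]
    onehot = np.eye(n, dtype=np.float32)[np.asarray(labels)]
    lp = log_softmax(logits)
    return neg(tmean(tsum(mul(lp, Tensor(onehot)), axis=-1)))


# -- the backward driver --------------------------------------------------

def _topo(out: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(out, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node._parents:
            if parent.requires_grad and id(parent) not in seen:
                stack.append((parent, False))
    return order


def grad(out: Tensor, wrt: Iterable[Tensor], create_graph: bool = False):
    """Gradients of a scalar ``out`` with respect to each tensor in ``wrt``.

    The returned gradients are :class:`Tensor` objects; when ``create_graph``
    is true they stay connected to the graph so they can be differentiated
    again (double backpropagation).
    """
    wrt = list(wrt)
    if out.data.size != 1:
        raise ValueError("grad expects a scalar output")
    grads: dict[int, Tensor] = {id(out): Tensor(np.ones_like(out.data))}
    for node in reversed(_topo(out)):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if not create_graph:
            g = g if not g.requires_grad else Tensor(g.data)
        for parent, vjp in node._parents:
            if not parent.requires_grad:
                continue
            pg = vjp(g)
            prev = grads.get(id(parent))
            grads[id(parent)] = pg if prev is None else add(prev, pg)
        # keep gradients of requested leaves
        if any(node is t for t in wrt):
            grads[id(node)] = g
    out_grads = []
    for t in wrt:
        g = grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        elif not create_graph and g.requires_grad:
            g = Tensor(g.data)
        out_grads.append(g)
    return out_grads
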