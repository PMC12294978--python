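"""Compact reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations that
produced it; :meth:`Tensor.backward` runs reverse-mode accumulation over the
resulting DAG.  The op set is exactly what the model needs: broadcasting
arithmetic, 2-D matmul, reductions, elementwise nonlinearities, concatenation,
row gather and segment-sum (the scatter/gather pair that makes disjoint-union
graph batching cheap), and numerically stable softplus / log-sum-exp building
blocks.

Everything is float64 and single-threaded NumPy, so identical seeds give
bitwise-identical results.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

Array = np.ndarray


def _as_array(x) -> Array:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: Array, shape: tuple) -> Array:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp", "name")

    def __init__(self, data, requires_grad: bool = False, *,
                 _parents: tuple = (), _vjp: Callable | None = None,
                 name: str | None = None):
        self.data = _as_array(data)
        self.grad: Array | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents)
        self._parents = _parents
        self._vjp = _vjp
        self.name = name

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff engine ------------------------------------------------------
    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        grads: dict[int, Array] = {id(self): _as_array(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._vjp is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        other = astensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(astensor(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    @property
    def T(self):
        return transpose(self)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data + b.data
    return Tensor(out, _parents=(a, b), _vjp=lambda g: (
        _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)))


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data * b.data
    return Tensor(out, _parents=(a, b), _vjp=lambda g: (
        _unbroadcast(g * b.data, a.data.shape),
        _unbroadcast(g * a.data, b.data.shape)))


def power(a, p: float) -> Tensor:
    a = astensor(a)
    out = a.data ** p
    return Tensor(out, _parents=(a,), _vjp=lambda g: (
        g * p * a.data ** (p - 1.0),))


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data @ b.data
    return Tensor(out, _parents=(a, b), _vjp=lambda g: (
        g @ b.data.T, a.data.T @ g))


def bmm(a, b) -> Tensor:
    """Batched matmul on stacks of matrices ([..., n, k] @ [..., k, m])."""
    a, b = astensor(a), astensor(b)
    out = a.data @ b.data
    return Tensor(out, _parents=(a, b), _vjp=lambda g: (
        g @ b.data.swapaxes(-1, -2), a.data.swapaxes(-1, -2) @ g))


def swapaxes_last(a) -> Tensor:
    """Swap the last two axes (batched matrix transpose)."""
    a = astensor(a)
    return Tensor(a.data.swapaxes(-1, -2), _parents=(a,),
                  _vjp=lambda g: (g.swapaxes(-1, -2),))


def transpose(a) -> Tensor:
    a = astensor(a)
    return Tensor(a.data.T, _parents=(a,), _vjp=lambda g: (g.T,))


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    return Tensor(a.data.reshape(shape), _parents=(a,),
                  _vjp=lambda g: (g.reshape(a.data.shape),))


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        gg = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(gg, a.data.shape).copy(),)

    return Tensor(out, _parents=(a,), _vjp=vjp)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def relu(a) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    return Tensor(a.data * mask, _parents=(a,), _vjp=lambda g: (g * mask,))


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    scale = np.where(mask, 1.0, slope)
    return Tensor(a.data * scale, _parents=(a,), _vjp=lambda g: (g * scale,))


def elu(a, alpha: float = 1.0) -> Tensor:
    a = astensor(a)
    neg = alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0)
    out = np.where(a.data > 0, a.data, neg)
    dout = np.where(a.data > 0, 1.0, neg + alpha)
    return Tensor(out, _parents=(a,), _vjp=lambda g: (g * dout,))


def tanh(a) -> Tensor:
    a = astensor(a)
    out = np.tanh(a.data)
    return Tensor(out, _parents=(a,), _vjp=lambda g: (g * (1.0 - out ** 2),))


def sigmoid(a) -> Tensor:
    a = astensor(a)
    out = 1.0 / (1.0 + np.exp(-np.abs(a.data)))
    out = np.where(a.data >= 0, out, 1.0 - out)
    return Tensor(out, _parents=(a,), _vjp=lambda g: (g * out * (1.0 - out),))


def exp(a) -> Tensor:
    a = astensor(a)
    out = np.exp(a.data)
    return Tensor(out, _parents=(a,), _vjp=lambda g: (g * out,))


def log(a) -> Tensor:
    a = astensor(a)
    return Tensor(np.log(a.data), _parents=(a,), _vjp=lambda g: (g / a.data,))


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def softplus(a) -> Tensor:
    """log(1 + e^x), computed stably; derivative is the logistic function."""
    a = astensor(a)
    out = np.maximum(a.data, 0.0) + np.log1p(np.exp(-np.abs(a.data)))
    sig = 1.0 / (1.0 + np.exp(-np.abs(a.data)))
    sig = np.where(a.data >= 0, sig, 1.0 - sig)
    return Tensor(out, _parents=(a,), _vjp=lambda g: (g * sig,))


def concat(tensors: Sequence, axis: int = 0) -> Tensor:
    ts = [astensor(t) for t in tensors]
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, _parents=tuple(ts), _vjp=vjp)


def _scatter_add(data: Array, idx: Array, num_segments: int) -> Array:
    """Sum rows of `data` into buckets; fast reduceat path for sorted ids."""
    shape = (num_segments,) + data.shape[1:]
    if idx.size == 0:
        return np.zeros(shape)
    if idx.size > 1 and np.all(idx[1:] >= idx[:-1]):
        counts = np.bincount(idx, minlength=num_segments)
        out = np.zeros(shape)
        nz = counts > 0
        starts = np.concatenate(([0], np.cumsum(counts)))[:-1]
        out[nz] = np.add.reduceat(data, starts[nz], axis=0)
        return out
    out = np.zeros(shape)
    np.add.at(out, idx, data)
    return out


def gather(a, idx) -> Tensor:
    """Row gather a[idx] along axis 0; the VJP scatter-adds."""
    a = astensor(a)
    idx = np.asarray(idx, dtype=np.intp)

    def vjp(g):
        return (_scatter_add(np.ascontiguousarray(g), idx, a.data.shape[0]),)

    return Tensor(a.data[idx], _parents=(a,), _vjp=vjp)


def segment_sum(a, segment_ids, num_segments: int) -> Tensor:
    """Sum rows of `a` into `num_segments` buckets given per-row ids."""
    a = astensor(a)
    seg = np.asarray(segment_ids, dtype=np.intp)
    out = _scatter_add(np.ascontiguousarray(a.data), seg, num_segments)
    return Tensor(out, _parents=(a,), _vjp=lambda g: (g[seg],))


def segment_mean(a, segment_ids, num_segments: int) -> Tensor:
    seg = np.asarray(segment_ids, dtype=np.intp)
    counts = np.bincount(seg, minlength=num_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    s = segment_sum(a, seg, num_segments)
    return mul(s, (1.0 / counts).reshape((-1,) + (1,) * (s.data.ndim - 1)))


def segment_softmax(logits, segment_ids, num_segments: int) -> Tensor:
    """Softmax of a 1-D logit vector within each segment.

    The per-segment max is treated as a constant shift (softmax is invariant
    to it), which keeps the computation stable without extra VJP machinery.
    """
    logits = astensor(logits)
    seg = np.asarray(segment_ids, dtype=np.intp)
    maxes = np.full(num_segments, -np.inf)
    np.maximum.at(maxes, seg, logits.data)
    maxes[~np.isfinite(maxes)] = 0.0
    shifted = add(logits, Tensor(-maxes[seg]))
    e = exp(shifted)
    denom = segment_sum(reshape(e, (-1, 1)), seg, num_segments)
    denom_g = gather(denom, seg)
    return mul(e, power(reshape(denom_g, (-1,)), -1.0))


def row_softmax(a) -> Tensor:
    """Softmax along the last axis of a 2-D tensor (stable, mask-friendly)."""
    a = astensor(a)
    shift = np.max(a.data, axis=-1, keepdims=True)
    e = exp(add(a, Tensor(-shift)))
    return mul(e, power(tsum(e, axis=-1, keepdims=True), -1.0))


def logsumexp_rows(a) -> Tensor:
    """Row-wise log-sum-exp of a 2-D tensor, stable via a detached max."""
    a = astensor(a)
    shift = np.max(a.data, axis=-1, keepdims=True)
    e = exp(add(a, Tensor(-shift)))
    return add(log(tsum(e, axis=-1)), Tensor(shift[:, 0]))


def dropout(a, rate: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return astensor(a)
    if rng is None:
        raise ValueError("dropout in training mode needs an rng")
    a = astensor(a)
    mask = (rng.random(a.data.shape) >= rate) / (1.0 - rate)
    return mul(a, Tensor(mask))
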