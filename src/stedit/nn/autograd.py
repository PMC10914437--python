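"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine supports the handful of primitives needed by the style-based
generator, the discriminator and the inversion encoders: elementwise
arithmetic, matmul, reductions, reshaping, slicing, gather/scatter and a few
nonlinearities.  Vector-Jacobian products are themselves expressed as Tensor
operations, so gradients can be differentiated again (double backprop).  That
property is required by the R1 gradient penalty and the path-length penalty,
both of which are losses defined on first-order gradients.

Design notes
------------
* ``grad(output, wrt)`` is functional: it returns gradient Tensors and never
  mutates state.  Optimizers read ``g.data``.
* Activation masks (leaky ReLU) are treated as constants in the second
  backward pass, which is exact almost everywhere.
* Everything is float64.  The networks here are tiny; numerical transparency
  in tests is worth more than speed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "grad",
    "concat",
    "leaky_relu",
    "sigmoid",
    "softplus",
    "logsumexp",
]


class Tensor:
    """An n-d array with an optional autodiff graph node."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._vjp = _vjp

    # ------------------------------------------------------------------ misc
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))
        out._vjp = lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._vjp = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))
        out._vjp = lambda g: (
            _unbroadcast(g * other, self.shape),
            _unbroadcast(g * self, other.shape),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))
        out._vjp = lambda g: (
            _unbroadcast(g / other, self.shape),
            _unbroadcast(-g * self / (other * other), other.shape),
        )
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data**exponent, _parents=(self,))
        out._vjp = lambda g: (g * (exponent * self ** (exponent - 1)),)
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))
        out._vjp = lambda g: (g @ other.T, self.T @ g)
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def vjp(g):
            gd = g
            if axis is not None and not keepdims:
                gd = gd.reshape(_keepdim_shape(self.shape, axis))
            return (gd.broadcast_to(self.shape),)

        out._vjp = vjp
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._vjp = lambda g: (g.reshape(self.shape),)
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._vjp = lambda g: (g.transpose(inv),)
        return out

    @property
    def T(self):
        return self.transpose()

    def broadcast_to(self, shape):
        out = Tensor(np.broadcast_to(self.data, shape), _parents=(self,))
        out._vjp = lambda g: (_unbroadcast(g, self.shape),)
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _parents=(self,))
        out._vjp = lambda g: (_slice_adjoint(g, key, self.shape),)
        return out

    # ---------------------------------------------------------- elementwise
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._vjp = lambda g: (g * out,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._vjp = lambda g: (g / self,)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _parents=(self,))
        out._vjp = lambda g: (g * (1.0 - out * out),)
        return out

    def sqrt(self):
        return self**0.5


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------- helpers
def _keepdim_shape(shape, axis):
    axes = {a % len(shape) for a in np.atleast_1d(axis)}
    return tuple(1 if i in axes else s for i, s in enumerate(shape))


def _unbroadcast(g: Tensor, target_shape) -> Tensor:
    """Sum ``g`` down to ``target_shape`` (adjoint of NumPy broadcasting)."""
    if g.shape == tuple(target_shape):
        return g
    extra = g.ndim - len(target_shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(
        i for i, (gs, ts) in enumerate(zip(g.shape, target_shape)) if ts == 1 and gs != 1
    )
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(target_shape) if g.shape != tuple(target_shape) else g


def _slice_adjoint(g: Tensor, key, shape) -> Tensor:
    """Adjoint of ``__getitem__``: scatter ``g`` into a zero array of ``shape``."""
    out = Tensor(np.zeros(shape), _parents=(g,))
    np.add.at(out.data, key, g.data)
    out._vjp = lambda gg: (gg[key],)
    return out


# ------------------------------------------------------------- nonlinearities
def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    mask = np.where(x.data > 0, 1.0, slope)
    out = Tensor(x.data * mask, _parents=(x,))
    out._vjp = lambda g: (g * Tensor(mask),)
    return out


def sigmoid(x: Tensor) -> Tensor:
    out = Tensor(1.0 / (1.0 + np.exp(-x.data)), _parents=(x,))
    out._vjp = lambda g: (g * (out * (1.0 - out)),)
    return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), numerically stable."""
    out = Tensor(np.logaddexp(0.0, x.data), _parents=(x,))
    out._vjp = lambda g: (g * sigmoid(x),)
    return out


def logsumexp(x: Tensor, axis: int = -1) -> Tensor:
    m = np.max(x.data, axis=axis, keepdims=True)
    s = (x - Tensor(m)).exp().sum(axis=axis)
    return s.log() + Tensor(np.squeeze(m, axis=axis))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        grads = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            key = [slice(None)] * g.ndim
            key[axis] = slice(int(lo), int(hi))
            grads.append(g[tuple(key)])
        return tuple(grads)

    out._vjp = vjp
    return out


# ------------------------------------------------------------------ backward
def grad(output: Tensor, wrt, grad_output=None):
    """Gradients of a scalar ``output`` with respect to each Tensor in ``wrt``.

    Returns a list of Tensors aligned with ``wrt``; entries are zero Tensors
    for inputs the output does not depend on.  The returned Tensors carry
    their own graph, so they can be differentiated again.
    """
    wrt = list(wrt)
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))

    topo: list[Tensor] = []
    visited: set[int] = set()
    stack = [(output, False)]
    needed = _reachable_from(output, wrt)
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited or id(node) not in needed:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))

    grads: dict[int, Tensor] = {id(output): grad_output}
    for node in reversed(topo):
        g = grads.get(id(node))
        if g is None or node._vjp is None:
            continue
        parent_grads = node._vjp(g)
        for p, pg in zip(node._parents, parent_grads):
            if pg is None or id(p) not in needed:
                continue
            if id(p) in grads:
                grads[id(p)] = grads[id(p)] + pg
            else:
                grads[id(p)] = pg

    return [grads.get(id(w), Tensor(np.zeros_like(w.data))) for w in wrt]


def _reachable_from(output: Tensor, wrt) -> set[int]:
    """ids of nodes on some path from ``output`` down to a ``wrt`` leaf."""
    wrt_ids = {id(w) for w in wrt}
    memo: dict[int, bool] = {}

    def visit(node: Tensor) -> bool:
        nid = id(node)
        if nid in memo:
            return memo[nid]
        memo[nid] = False  # cycle guard; graphs are DAGs but be safe
        hits = [visit(p) for p in node._parents]  # no short-circuit: every
        hit = nid in wrt_ids or any(hits)         # branch must be explored
        memo[nid] = hit
        return hit

    # iterative wrapper to dodge recursion limits on deep graphs
    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 100000))
    try:
        visit(output)
    finally:
        sys.setrecursionlimit(old)
    return {nid for nid, ok in memo.items() if ok}
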