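"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the package's models need: broadcasted
arithmetic, batched matmul, reductions, softmax / log-softmax with fused
cross-entropy, layer norm, embedding lookup, and a handful of pointwise
nonlinearities.  float32 throughout.
"""

from __future__ import annotations

import numpy as np

_DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(
            requires_grad or any(p.requires_grad for p in _parents)
        )
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(_DTYPE, copy=True)
        else:
            self.grad += grad

    # -- autograd driver ----------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, _parents=(self,))

        def bwd(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = bwd
        return out

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), _parents=(self,))
        out._backward = lambda g: self._accum(np.swapaxes(g, a, b))
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis=axis)
            self._accum(np.broadcast_to(g, self.shape).astype(_DTYPE))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, _parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - t * t))
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _parents=(self,))

        def bwd(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))

        out._backward = bwd
        return out


# -- free functions ----------------------------------------------------------

def cat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bwd
    return out


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather with scatter-add backward; `ids` is an integer array."""
    ids = np.asarray(ids)
    out = Tensor(weight.data[ids], _parents=(weight,))

    def bwd(g):
        acc = np.zeros_like(weight.data)
        np.add.at(acc, ids.reshape(-1), g.reshape(-1, weight.data.shape[1]))
        weight._accum(acc)

    out._backward = bwd
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data, _parents=(x, gamma, beta))
    d = x.data.shape[-1]

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            gx = g * gamma.data
            term = gx - gx.mean(axis=-1, keepdims=True) \
                - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            x._accum(term * inv)

    out._backward = bwd
    return out


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray,
                          weights: np.ndarray | None = None) -> Tensor:
    """Mean cross-entropy over positions with nonzero weight.

    logits: (..., V); targets: integer array broadcastable to logits[:-1];
    weights: same shape as targets, 0 excludes a position (e.g. PAD).
    """
    targets = np.asarray(targets)
    flat_logits = logits.data.reshape(-1, logits.data.shape[-1])
    flat_t = targets.reshape(-1)
    if weights is None:
        w = np.ones(flat_t.shape, dtype=_DTYPE)
    else:
        w = np.asarray(weights, dtype=_DTYPE).reshape(-1)
    n_eff = max(w.sum(), 1.0)
    z = flat_logits - flat_logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    nll = (lse - z[np.arange(flat_t.size), flat_t]) * w
    out = Tensor(nll.sum() / n_eff, _parents=(logits,))

    def bwd(g):
        p = np.exp(z - lse[:, None])
        p[np.arange(flat_t.size), flat_t] -= 1.0
        p *= (w / n_eff)[:, None]
        logits._accum((g * p).reshape(logits.data.shape))

    out._backward = bwd
    return out


def binary_cross_entropy_with_logits(logits: Tensor, targets: np.ndarray,
                                     weights: np.ndarray | None = None
                                     ) -> Tensor:
    """Numerically stable weighted mean BCE from raw logits."""
    t = np.asarray(targets, dtype=_DTYPE)
    x = logits.data
    w = np.ones_like(t) if weights is None else \
        np.asarray(weights, dtype=_DTYPE)
    w_sum = max(float(w.sum()), 1e-12)
    loss = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
    out = Tensor((loss * w).sum() / w_sum, _parents=(logits,))

    def bwd(g):
        s = 1.0 / (1.0 + np.exp(-x))
        logits._accum(g * w * (s - t) / w_sum)

    out._backward = bwd
    return out
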