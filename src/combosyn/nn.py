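"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module is the numerical core the graph encoders, fusion head,
training loop and integrated-gradients attribution are built on.  It
implements exactly the operator set those components need: broadcasting
arithmetic, matrix products, the standard nonlinearities, reductions,
concatenation, row gather and masked row-softmax.  Gradients are
accumulated by topological-order backpropagation from a scalar loss.

All arrays are float64; determinism follows from NumPy determinism.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "concat",
    "stack_rows",
    "row_softmax",
    "Adam",
    "glorot",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad=None):
        """Backpropagate from this tensor (scalar unless `grad` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for parent, pg in t._backward(g):
                if not (parent.requires_grad or parent._backward or parent._parents):
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        out._backward = lambda g: [
            (self, _unbroadcast(g, self.data.shape)),
            (other, _unbroadcast(g, other.data.shape)),
        ]
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: [(self, -g)]
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        out._backward = lambda g: [
            (self, _unbroadcast(g * other.data, self.data.shape)),
            (other, _unbroadcast(g * self.data, other.data.shape)),
        ]
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        out._backward = lambda g: [
            (self, _unbroadcast(g / other.data, self.data.shape)),
            (other, _unbroadcast(-g * self.data / other.data**2, other.data.shape)),
        ]
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))
        out._backward = lambda g: [(self, g * exponent * self.data ** (exponent - 1))]
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        out._backward = lambda g: [
            (self, g @ other.data.T),
            (other, self.data.T @ g),
        ]
        return out

    # -- nonlinearities -------------------------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: [(self, g * (self.data > 0))]
        return out

    def leaky_relu(self, negative_slope: float = 0.2):
        out = Tensor(
            np.where(self.data > 0, self.data, negative_slope * self.data),
            parents=(self,),
        )
        out._backward = lambda g: [
            (self, g * np.where(self.data > 0, 1.0, negative_slope))
        ]
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: [(self, g * s * (1.0 - s))]
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))
        out._backward = lambda g: [(self, g * (1.0 - t**2))]
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))
        out._backward = lambda g: [(self, g * e)]
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: [(self, g / self.data)]
        return out

    # -- reductions and shaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return [(self, np.broadcast_to(g, self.data.shape).copy())]

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: [(self, g.reshape(self.data.shape))]
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, parents=(self,))
        out._backward = lambda g: [(self, g.T)]
        return out

    def take_rows(self, idx):
        """Gather rows by integer index (with repetition)."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            return [(self, acc)]

        out._backward = bwd
        return out

    def slice_cols(self, start: int, stop: int):
        out = Tensor(self.data[:, start:stop], parents=(self,))

        def bwd(g):
            acc = np.zeros_like(self.data)
            acc[:, start:stop] = g
            return [(self, acc)]

        out._backward = bwd
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis` (differentiable)."""
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    bounds = np.cumsum([0] + sizes)

    def bwd(g):
        pieces = []
        for t, a, b in zip(tensors, bounds[:-1], bounds[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            pieces.append((t, g[tuple(sl)]))
        return pieces

    out._backward = bwd
    return out


def stack_rows(vectors) -> Tensor:
    """Stack 1-D (or (1,d)) tensors into a matrix, one per row."""
    rows = [v.reshape(1, -1) if v.ndim == 1 else v for v in vectors]
    return concat(rows, axis=0)


def row_softmax(logits: Tensor, mask: np.ndarray) -> Tensor:
    """Softmax along axis 1 restricted to positions where ``mask`` is truthy.

    Masked-out entries get probability exactly 0.  Numerically stabilised
    by subtracting the per-row masked maximum (a constant, so it does not
    affect gradients).
    """
    mask = np.asarray(mask, dtype=bool)
    neg = np.where(mask, 0.0, -np.inf)
    shifted_max = np.max(np.where(mask, logits.data, -np.inf), axis=1, keepdims=True)
    shifted_max = np.where(np.isfinite(shifted_max), shifted_max, 0.0)
    z = logits + Tensor(neg - shifted_max)
    # exp(-inf) = 0 removes masked entries from numerator and denominator
    with np.errstate(invalid="ignore"):
        e = z.exp()
    denom = e.sum(axis=1, keepdims=True)
    return e / denom


# -- parameter initialisation and optimisation --------------------------------


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Uniform Glorot/Xavier initialisation."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Adam:
    """Adaptive-moment gradient descent over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
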