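"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The generative model (expression encoder, graph-attention encoder, state and
time networks, Gaussian-mixture likelihood) is trained by gradient descent;
this module supplies the tape. It is deliberately small: dense float64
arrays, a handful of ops (arithmetic with broadcasting, matmul, exp/log,
activations, reductions, gather/scatter for graph message passing, and the
special functions needed for Dirichlet KL terms).

Every op builds a ``Tensor`` node holding its parents and a vector-Jacobian
closure; ``Tensor.backward`` runs the tape in reverse topological order.
Gradients are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = ["Tensor", "as_tensor", "exp", "log", "softplus", "sigmoid"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_vjp")
    __array_priority__ = 100.0

    def __init__(self, data, parents=(), vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._vjp = vjp  # callable(g) -> tuple of grads, one per parent

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self):
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"

    def backward(self, grad=None):
        """Accumulate gradients of ``self`` w.r.t. every ancestor."""
        if grad is None:
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._vjp(node.grad)):
                if g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.array(g, dtype=np.float64)
                else:
                    parent.grad = parent.grad + g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))
        out._vjp = lambda g: (
            _unbroadcast(g, self.data.shape),
            _unbroadcast(g, other.data.shape),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._vjp = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))
        out._vjp = lambda g: (
            _unbroadcast(g * other.data, self.data.shape),
            _unbroadcast(g * self.data, other.data.shape),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, (self, other))
        out._vjp = lambda g: (
            _unbroadcast(g / other.data, self.data.shape),
            _unbroadcast(-g * self.data / other.data**2, other.data.shape),
        )
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, (self,))
        out._vjp = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, (self, other))
        out._vjp = lambda g: (g @ other.data.T, self.data.T @ g)
        return out

    # ------------------------------------------------------------- elementwise
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, (self,))
        out._vjp = lambda g: (g * val,)
        return out

    def expm1(self):
        val = np.expm1(self.data)
        out = Tensor(val, (self,))
        out._vjp = lambda g: (g * (val + 1.0),)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._vjp = lambda g: (g / self.data,)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, (self,))
        out._vjp = lambda g: (g / (2.0 * val),)
        return out

    def sigmoid(self):
        val = special.expit(self.data)
        out = Tensor(val, (self,))
        out._vjp = lambda g: (g * val * (1.0 - val),)
        return out

    def softplus(self):
        val = np.logaddexp(0.0, self.data)
        out = Tensor(val, (self,))
        sig = special.expit(self.data)
        out._vjp = lambda g: (g * sig,)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, (self,))
        out._vjp = lambda g: (g * (1.0 - val**2),)
        return out

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        val = np.where(pos, self.data, alpha * np.expm1(self.data))
        out = Tensor(val, (self,))
        out._vjp = lambda g: (g * np.where(pos, 1.0, val + alpha),)
        return out

    def leaky_relu(self, slope: float = 0.2):
        pos = self.data > 0
        out = Tensor(np.where(pos, self.data, slope * self.data), (self,))
        out._vjp = lambda g: (g * np.where(pos, 1.0, slope),)
        return out

    def gammaln(self):
        out = Tensor(special.gammaln(self.data), (self,))
        out._vjp = lambda g: (g * special.digamma(self.data),)
        return out

    def digamma(self):
        out = Tensor(special.digamma(self.data), (self,))
        out._vjp = lambda g: (g * special.polygamma(1, self.data),)
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        out._vjp = vjp
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def logsumexp(self, axis: int):
        m = np.max(self.data, axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        e = np.exp(self.data - m)
        s = e.sum(axis=axis, keepdims=True)
        val = np.squeeze(m + np.log(s), axis=axis)
        out = Tensor(val, (self,))
        soft = e / s
        out._vjp = lambda g: (np.expand_dims(g, axis) * soft,)
        return out

    # ------------------------------------------------------------ shape / index
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._vjp = lambda g: (g.reshape(self.data.shape),)
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, (self,))
        out._vjp = lambda g: (g.T,)
        return out

    def take_rows(self, idx: np.ndarray):
        """Gather rows (axis 0); gradient scatter-adds back."""
        idx = np.asarray(idx)
        out = Tensor(self.data[idx], (self,))

        def vjp(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            return (acc,)

        out._vjp = vjp
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], (self,))

        def vjp(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, key, g)
            return (acc,)

        out._vjp = vjp
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# dispatching helpers so closed-form kinetics work on ndarray and Tensor alike
# ---------------------------------------------------------------------------

def exp(x):
    return x.exp() if isinstance(x, Tensor) else np.exp(x)


def expm1(x):
    return x.expm1() if isinstance(x, Tensor) else np.expm1(x)


def log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def softplus(x):
    return x.softplus() if isinstance(x, Tensor) else np.logaddexp(0.0, x)


def sigmoid(x):
    return x.sigmoid() if isinstance(x, Tensor) else special.expit(x)


# ---------------------------------------------------------------------------
# graph ops
# ---------------------------------------------------------------------------

def scatter_sum(values: Tensor, index: np.ndarray, n: int) -> Tensor:
    """Sum edge values (E, ...) into node slots (n, ...)."""
    values = as_tensor(values)
    acc = np.zeros((n,) + values.data.shape[1:])
    np.add.at(acc, index, values.data)
    out = Tensor(acc, (values,))
    out._vjp = lambda g: (g[index],)
    return out


def segment_softmax(scores: Tensor, index: np.ndarray, n: int,
                    weights: np.ndarray | None = None) -> Tensor:
    """Softmax of edge scores within each target-node segment.

    Optional non-negative per-edge ``weights`` multiply the exponentiated
    scores before normalisation (weighted attention); zero-weight edges get
    zero attention.
    """
    scores = as_tensor(scores)
    x = scores.data
    m = np.full(n, -np.inf)
    np.maximum.at(m, index, x)
    m = np.where(np.isfinite(m), m, 0.0)
    e = np.exp(x - m[index])
    if weights is not None:
        e = e * weights
    denom = np.zeros(n)
    np.add.at(denom, index, e)
    denom = np.where(denom > 0, denom, 1.0)
    alpha = e / denom[index]
    out = Tensor(alpha, (scores,))

    def vjp(g):
        dot = np.zeros(n)
        np.add.at(dot, index, alpha * g)
        return (alpha * (g - dot[index]),)

    out._vjp = vjp
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._vjp = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))
    out._vjp = lambda g: tuple(np.moveaxis(g, axis, 0))
    return out
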