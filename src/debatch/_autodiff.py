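"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the batch-removal models need: dense affine
maps, rectifier nonlinearities, elementwise arithmetic, reductions, row
lookup into an embedding table, fused softmax cross-entropy, and a gradient
reversal node (identity forward, ``-lambda`` times the gradient backward).
Gradient correctness is pinned by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Linear", "Dropout", "Adam", "grad_reverse",
           "cross_entropy", "relu", "concat_params"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- graph plumbing ----------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _parents=(self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _parents=(self, other))
        out._backward = lambda g: (self._accum(g * other.data),
                                   other._accum(g * self.data))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, _parents=(self, other))
        out._backward = lambda g: (
            self._accum(g / other.data),
            other._accum(-g * self.data / other.data ** 2))
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, _parents=(self,))
        out._backward = lambda g: self._accum(
            g * exponent * self.data ** (exponent - 1))
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))
        out._backward = lambda g: (self._accum(g @ other.data.T),
                                   other._accum(self.data.T @ g))
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = back
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def take_rows(self, idx: np.ndarray) -> "Tensor":
        """Row lookup (embedding-table style); gradient scatter-adds."""
        idx = np.asarray(idx, dtype=int)
        out = Tensor(self.data[idx], _parents=(self,))

        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = back
        return out

    def item(self) -> float:
        return float(self.data)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, _parents=(x,))
    out._backward = lambda g: x._accum(g * mask)
    return out


def grad_reverse(x: Tensor, lam: float) -> Tensor:
    """Identity forward; multiplies the upstream gradient by ``-lam``."""
    if not np.isfinite(lam):
        raise ValueError("gradient reversal strength must be finite")
    out = Tensor(x.data, _parents=(x,))
    out._backward = lambda g: x._accum(-lam * g)
    return out


def cross_entropy(logits: Tensor, targets: np.ndarray, *,
                  label_smoothing: float = 0.0,
                  sample_weight: np.ndarray | None = None) -> Tensor:
    """Mean softmax cross-entropy with optional label smoothing and weights.

    `targets` are integer class indices. With smoothing s and C classes the
    target distribution is (1-s) on the true class and s/C everywhere.
    """
    n, c = logits.data.shape
    targets = np.asarray(targets, dtype=int)
    t = np.full((n, c), label_smoothing / c)
    t[np.arange(n), targets] += 1.0 - label_smoothing
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    w = w / w.sum()

    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    value = -(w[:, None] * t * logp).sum()
    out = Tensor(value, _parents=(logits,))
    softmax = np.exp(logp)
    out._backward = lambda g: logits._accum(g * w[:, None] * (softmax - t))
    return out


class Linear:
    """Dense affine layer, He-initialized."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Parameter(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class Dropout:
    """Inverted dropout; active only when train=True is passed at call."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if not train or self.p == 0.0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Adam:
    """Adam with decoupled (AdamW-style) weight decay."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)


def concat_params(*module_groups):
    out = []
    for grp in module_groups:
        out.extend(grp)
    return out
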