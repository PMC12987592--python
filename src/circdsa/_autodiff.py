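"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the graph-convolutional encoders, the structure
learner and the losses used in this package: dense float64 tensors, a tape
built implicitly through parent links, and an Adam optimizer.  Gradients of
every primitive are checked against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the local backward rules that produced it."""

    __slots__ = ("data", "grad", "_parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents  # tuple of (Tensor, fn(upstream)->grad wrt parent)
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in parents)

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p, _ in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            for p, fn in t._parents:
                if p.requires_grad:
                    p.grad = p.grad + _unbroadcast(np.asarray(fn(t.grad)), p.data.shape)

    # -- coercion --------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        o = self._wrap(other)
        return Tensor(self.data + o.data,
                      ((self, lambda g: g), (o, lambda g: g)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, ((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        o = self._wrap(other)
        return Tensor(self.data * o.data,
                      ((self, lambda g: g * o.data), (o, lambda g: g * self.data)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._wrap(other)
        return self * o._pow_const(-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self._pow_const(-1.0)

    def __matmul__(self, other):
        o = self._wrap(other)
        return Tensor(self.data @ o.data,
                      ((self, lambda g: g @ o.data.T), (o, lambda g: self.data.T @ g)))

    def _pow_const(self, p: float):
        base = self.data
        return Tensor(base ** p, ((self, lambda g: g * p * base ** (p - 1.0)),))

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents supported")
        return self._pow_const(float(p))

    # -- shaping ---------------------------------------------------------
    @property
    def T(self):
        return Tensor(self.data.T, ((self, lambda g: g.T),))

    def sum(self, axis=None, keepdims=False):
        def back(g):
            if axis is None:
                return np.full_like(self.data, 1.0) * g
            if not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, self.data.shape)
        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), ((self, back),))

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def rows(self, idx: np.ndarray):
        idx = np.asarray(idx)

        def back(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return out
        return Tensor(self.data[idx], ((self, back),))

    def gather(self, r: np.ndarray, c: np.ndarray):
        """Pick elements self[r, c] as a 1-D tensor."""
        r = np.asarray(r)
        c = np.asarray(c)

        def back(g):
            out = np.zeros_like(self.data)
            np.add.at(out, (r, c), g)
            return out
        return Tensor(self.data[r, c], ((self, back),))

    # -- nonlinearities --------------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, ((self, lambda g: g * out),))

    def log(self):
        return Tensor(np.log(self.data), ((self, lambda g: g / self.data),))

    def sqrt(self):
        return self._pow_const(0.5)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(out, ((self, lambda g: g * out * (1.0 - out)),))

    def relu(self):
        mask = self.data > 0
        return Tensor(np.where(mask, self.data, 0.0), ((self, lambda g: g * mask),))

    def elu(self, alpha: float = 1.0):
        x = self.data
        neg = alpha * (np.exp(np.minimum(x, 0.0)) - 1.0)
        out = np.where(x > 0, x, neg)
        dx = np.where(x > 0, 1.0, neg + alpha)
        return Tensor(out, ((self, lambda g: g * dx),))


# -- composites -----------------------------------------------------------

def log_softmax(z: Tensor) -> Tensor:
    """Row-wise log-softmax; the per-row max is treated as a constant shift."""
    m = Tensor(z.data.max(axis=1, keepdims=True))
    e = (z - m).exp()
    return (z - m) - e.sum(axis=1, keepdims=True).log()


def l2_normalize_rows(z: Tensor, eps: float = 1e-12) -> Tensor:
    sq = (z * z).sum(axis=1, keepdims=True)
    return z * (sq + eps) ** -0.5


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return parameter(rng.uniform(-lim, lim, size=(fan_in, fan_out)))


class Adam:
    """Adam with bias correction; operates in place on a fixed parameter list."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
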