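"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery (dense ops, broadcasting, a piecewise-linear op for
the fitted flow transforms) to train the small encoder/decoder/surrogate
networks with composite losses, including a Pearson-correlation bonus term.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("value", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, value, parents=(), requires_grad=False, backward=None):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.value.shape

    # -- graph --------------------------------------------------------------

    def backward(self) -> None:
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.value)
        self.grad = np.ones_like(self.value)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.value + other.value, (self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.value.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.value.shape)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += -g

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value * other.value, (self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.value, self.value.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.value, other.value.shape)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.value / other.value, (self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.value, self.value.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(-g * self.value / other.value**2,
                                           other.value.shape)

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value @ other.value, (self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += g @ other.value.T
            if other.requires_grad:
                other.grad += self.value.T @ g

        out._backward = bw
        return out

    def square(self):
        out = Tensor(self.value**2, (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * 2.0 * self.value

        out._backward = bw
        return out

    def sqrt(self):
        val = np.sqrt(self.value)
        out = Tensor(val, (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * 0.5 / np.maximum(val, 1e-300)

        out._backward = bw
        return out

    def abs(self):
        out = Tensor(np.abs(self.value), (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * np.sign(self.value)

        out._backward = bw
        return out

    def tanh(self):
        val = np.tanh(self.value)
        out = Tensor(val, (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * (1.0 - val**2)

        out._backward = bw
        return out

    def sum(self):
        out = Tensor(self.value.sum(), (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * np.ones_like(self.value)

        out._backward = bw
        return out

    def mean(self):
        n = self.value.size
        out = Tensor(self.value.mean(), (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * np.ones_like(self.value) / n

        out._backward = bw
        return out

    def piecewise_linear(self, xs: np.ndarray, ys: np.ndarray):
        """Apply a fixed monotone piecewise-linear map elementwise; the
        gradient is the local slope (edge slopes are extended outside the
        knot range)."""
        xs = np.asarray(xs, float)
        ys = np.asarray(ys, float)
        slopes = np.diff(ys) / np.diff(xs)
        x = self.value
        j = np.clip(np.searchsorted(xs, x) - 1, 0, len(slopes) - 1)
        val = ys[j] + slopes[j] * (x - xs[j])
        out = Tensor(val, (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * slopes[j]

        out._backward = bw
        return out


def mse(a: Tensor, b: Tensor) -> Tensor:
    return (a - b).square().mean()


def pearson(const_values: np.ndarray, b: Tensor) -> Tensor:
    """Pearson correlation between a constant vector and a tensor."""
    a = np.asarray(const_values, float).ravel()
    ac = Tensor(a - a.mean())
    bc = b - b.mean()
    num = (ac * bc).sum()
    den = ((ac * ac).sum() * (bc * bc).sum()).sqrt() + 1e-30
    return num / den


class Adam:
    """Adam optimizer over a flat list of Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
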