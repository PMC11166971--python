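"""Minimal reverse-mode automatic differentiation over numpy arrays.

The diagnosis model is small (a couple of graph-attention layers, an
additive-attention fusion and a linear classifier over per-dialogue
graphs of a few dozen nodes), so a compact tape-based engine over dense
numpy arrays is sufficient and keeps the package dependency-light. The
op set is exactly what the model needs: broadcasting arithmetic, matmul,
tanh / leaky-ReLU, exp / log with clamping, reductions, concatenation,
indexing and a mask-aware softmax. Gradient correctness is established
against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "concat", "masked_softmax", "Adam", "glorot", "param"]

Array = np.ndarray


def _as_array(x) -> Array:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[Array], None] | None = None):
        self.data = _as_array(data)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Array | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
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
        self._accumulate(np.ones_like(self.data) if grad is None else _as_array(grad))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic -------------------------------------------------------

    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = fwd(self.data, other.data)
        out = Tensor(out_data, parents=(self, other))

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(bwd_self(g, self.data, other.data), self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(bwd_other(g, self.data, other.data), other.shape))

        out._backward = backward
        return out

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b,
                            lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b,
                            lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b,
                            lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b,
                            lambda g, a, b: g / b, lambda g, a, b: -g * a / (b * b))

    def __neg__(self):
        return self * -1.0

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g: Array) -> None:
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim == 1 and g.ndim == a.ndim - 1:
                    self._accumulate(np.expand_dims(g, -1) * b)
                else:
                    self._accumulate(g @ np.swapaxes(b, -1, -2) if b.ndim > 1
                                     else np.outer(g, b).reshape(a.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    other._accumulate(np.outer(a, g) if b.ndim > 1 else a * g)
                else:
                    other._accumulate(np.swapaxes(a, -1, -2) @ g if g.ndim > 1
                                      else a.T @ g)

        out._backward = backward
        return out

    # -- elementwise nonlinearities --------------------------------------

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - y * y))
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        y = np.where(self.data > 0, self.data, slope * self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(
            g * np.where(self.data > 0, 1.0, slope))
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * y)
        return out

    def log(self, clamp: float = 0.0) -> "Tensor":
        """Natural log; with ``clamp`` > 0, inputs are floored for stability
        (gradient is zero at clamped entries)."""
        x = np.maximum(self.data, clamp) if clamp > 0 else self.data
        out = Tensor(np.log(x), parents=(self,))
        active = (self.data >= clamp) if clamp > 0 else np.ones_like(x, dtype=bool)
        out._backward = lambda g: self._accumulate(g * active / np.maximum(x, 1e-300))
        return out

    # -- reductions & shaping --------------------------------------------

    def sum(self, axis=None) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis), parents=(self,))

        def backward(g: Array) -> None:
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                self._accumulate(np.broadcast_to(np.expand_dims(g, axis), self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))

        def backward(g: Array) -> None:
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = backward
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g: Array) -> None:
        offset = 0
        for t, size in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(offset, offset + size)
                t._accumulate(g[tuple(sl)])
            offset += size

    out._backward = backward
    return out


def masked_softmax(scores: Tensor, mask: Array, axis: int = -1) -> Tensor:
    """Row-wise softmax restricted to ``mask`` (boolean); masked entries get 0.

    Rows with no allowed entry yield all zeros rather than NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    x = np.where(mask, scores.data, -np.inf)
    xmax = np.max(x, axis=axis, keepdims=True)
    xmax = np.where(np.isfinite(xmax), xmax, 0.0)
    ex = np.exp(x - xmax) * mask
    denom = ex.sum(axis=axis, keepdims=True)
    y = np.divide(ex, denom, out=np.zeros_like(ex), where=denom > 0)
    out = Tensor(y, parents=(scores,))

    def backward(g: Array) -> None:
        # d softmax: y * (g - sum(g*y))
        dot = (g * y).sum(axis=axis, keepdims=True)
        scores._accumulate(y * (g - dot))

    out._backward = backward
    return out


def param(data: Array) -> Tensor:
    return Tensor(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> Array:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


class Adam:
    """Adaptive-moment first-order optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
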