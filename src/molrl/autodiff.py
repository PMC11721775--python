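"""Minimal reverse-mode automatic differentiation over numpy arrays.

The policy/value networks here are small (a handful of 64-wide matrix
products per molecular graph), so a compact tape-based autodiff is all
that is needed.  Everything is float64; gradients are checked against
central finite differences in the test suite.

Only the operations the networks use are provided: (broadcasting)
add/mul, matmul, relu, exp/log, reductions, row gather, concatenation,
log-softmax, clip and elementwise minimum.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np

ArrayLike = Union[float, int, np.ndarray, "Tensor"]

_grad_enabled = True


class no_grad:
    """Context manager disabling tape construction (fast inference)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence[tuple["Tensor", Callable]] = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        if parents and not _grad_enabled:
            parents = ()
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in parents)
        self._parents = tuple(p for p in parents if p[0].requires_grad)

    # -- basic protocol ----------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff core ------------------------------------------------

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            seen.add(id(t))
            stack = [(t, iter(t._parents))]
            while stack:
                node, it = stack[-1]
                advanced = False
                for parent, _ in it:
                    if id(parent) not in seen:
                        seen.add(id(parent))
                        stack.append((parent, iter(parent._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for parent, fn in node._parents:
                contrib = fn(g)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + contrib
                else:
                    grads[key] = contrib

    def zero_grad(self):
        self.grad = None

    # -- operators -----------------------------------------------------

    def __add__(self, other: ArrayLike) -> "Tensor":
        o = as_tensor(other)
        return Tensor(
            self.data + o.data,
            parents=[
                (self, lambda g: _unbroadcast(g, self.shape)),
                (o, lambda g: _unbroadcast(g, o.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor(-self.data, parents=[(self, lambda g: -g)])

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other: ArrayLike) -> "Tensor":
        o = as_tensor(other)
        return Tensor(
            self.data * o.data,
            parents=[
                (self, lambda g: _unbroadcast(g * o.data, self.shape)),
                (o, lambda g: _unbroadcast(g * self.data, o.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        o = as_tensor(other)
        return Tensor(
            self.data / o.data,
            parents=[
                (self, lambda g: _unbroadcast(g / o.data, self.shape)),
                (o, lambda g: _unbroadcast(-g * self.data / (o.data ** 2), o.shape)),
            ],
        )

    def __matmul__(self, other: "Tensor") -> "Tensor":
        o = as_tensor(other)
        return Tensor(
            self.data @ o.data,
            parents=[
                (self, lambda g: g @ o.data.T),
                (o, lambda g: self.data.T @ g),
            ],
        )

    def sum(self, axis=None) -> "Tensor":
        def back(g):
            if axis is None:
                return np.full(self.shape, g)
            return np.broadcast_to(np.expand_dims(g, axis), self.shape).copy()
        return Tensor(self.data.sum(axis=axis), parents=[(self, back)])

    def mean(self, axis=None) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)


def as_tensor(x: ArrayLike) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# Functions
# ---------------------------------------------------------------------------

def relu(t: Tensor) -> Tensor:
    mask = t.data > 0
    return Tensor(t.data * mask, parents=[(t, lambda g: g * mask)])


def exp(t: Tensor) -> Tensor:
    out = np.exp(t.data)
    return Tensor(out, parents=[(t, lambda g: g * out)])


def log(t: Tensor) -> Tensor:
    return Tensor(np.log(t.data), parents=[(t, lambda g: g / t.data)])


def tanh(t: Tensor) -> Tensor:
    out = np.tanh(t.data)
    return Tensor(out, parents=[(t, lambda g: g * (1.0 - out ** 2))])


def square(t: Tensor) -> Tensor:
    return t * t


def take_rows(t: Tensor, idx) -> Tensor:
    idx = np.asarray(idx, dtype=int)

    def back(g):
        out = np.zeros_like(t.data)
        np.add.at(out, idx, g)
        return out

    return Tensor(t.data[idx], parents=[(t, back)])


def gather(t: Tensor, index: int) -> Tensor:
    """Pick a single element of a 1-D tensor as a scalar tensor."""

    def back(g):
        out = np.zeros_like(t.data)
        out[index] = g
        return out

    return Tensor(t.data[index], parents=[(t, back)])


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    parents = []
    for k, t in enumerate(tensors):
        lo, hi = offsets[k], offsets[k + 1]

        def back(g, lo=lo, hi=hi):
            slicer = [slice(None)] * g.ndim
            slicer[axis] = slice(lo, hi)
            return g[tuple(slicer)]

        parents.append((t, back))
    return Tensor(out, parents=parents)


def stack_scalars(tensors: Sequence[Tensor]) -> Tensor:
    out = np.array([float(t.data) for t in tensors])
    parents = []
    for k, t in enumerate(tensors):
        parents.append((t, lambda g, k=k: np.asarray(g[k])))
    return Tensor(out, parents=parents)


def log_softmax(t: Tensor, mask: Optional[np.ndarray] = None) -> Tensor:
    """Log-softmax over the last axis; masked entries get -inf logits.

    ``mask`` is a boolean array (True = legal).  Gradients flow only
    through unmasked entries.
    """
    z = t.data.copy()
    if mask is not None:
        z = np.where(mask, z, -np.inf)
    zmax = np.max(z, axis=-1, keepdims=True)
    zmax = np.where(np.isfinite(zmax), zmax, 0.0)  # rows with no legal entry
    with np.errstate(invalid="ignore", divide="ignore"):
        zs = z - zmax
        lse = np.log(np.exp(zs).sum(axis=-1, keepdims=True))
        out = zs - lse
        p = np.where(np.isfinite(out), np.exp(out), 0.0)

    def back(g):
        gsum = g.sum(axis=-1, keepdims=True)
        grad = g - p * gsum
        if mask is not None:
            grad = np.where(mask, grad, 0.0)
        return grad

    return Tensor(out, parents=[(t, back)])


def clip(t: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp; gradient is passed through inside the interval only."""
    inside = (t.data > lo) & (t.data < hi)
    return Tensor(np.clip(t.data, lo, hi), parents=[(t, lambda g: g * inside)])


def minimum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise min, gradient routed to the smaller argument (ties → a)."""
    take_a = a.data <= b.data
    return Tensor(
        np.minimum(a.data, b.data),
        parents=[
            (a, lambda g: _unbroadcast(g * take_a, a.shape)),
            (b, lambda g: _unbroadcast(g * ~take_a, b.shape)),
        ],
    )


# ---------------------------------------------------------------------------
# Parameters and optimization
# ---------------------------------------------------------------------------

def parameter(array: np.ndarray) -> Tensor:
    return Tensor(array, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    """Uniform Glorot-style fan-scaled initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return parameter(rng.uniform(-limit, limit, size=(fan_in, fan_out)))


class Adam:
    """Adam optimizer over a name → Tensor parameter mapping."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()

    def step(self):
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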