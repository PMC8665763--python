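"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the primitives the DTI model needs: broadcast-aware
elementwise arithmetic, dense and constant-sparse matrix products, reductions,
row gather / segment-sum (the two halves of message passing on edge lists),
and the activations used by the layers. Everything is float64; gradients are
accumulated on leaf tensors with ``requires_grad=True`` by calling
``backward()`` on a scalar.

The engine is deliberately small: no in-place ops, no higher-order
derivatives, no GPU.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

ArrayLike = "np.ndarray | float | int | Sequence"


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- introspection -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd ----------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(other, self)

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_graph(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._backward is not None for t in tensors)


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _needs_graph(*parents):
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# Elementwise arithmetic


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def backward(g):
        return ((a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape)))

    return _node(out, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data - b.data

    def backward(g):
        return ((a, _unbroadcast(g, a.shape)), (b, _unbroadcast(-g, b.shape)))

    return _node(out, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def backward(g):
        return (
            (a, _unbroadcast(g * b.data, a.shape)),
            (b, _unbroadcast(g * a.data, b.shape)),
        )

    return _node(out, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data / b.data

    def backward(g):
        return (
            (a, _unbroadcast(g / b.data, a.shape)),
            (b, _unbroadcast(-g * a.data / (b.data**2), b.shape)),
        )

    return _node(out, (a, b), backward)


def pow_const(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out = a.data**exponent

    def backward(g):
        return ((a, g * exponent * a.data ** (exponent - 1)),)

    return _node(out, (a,), backward)


def sqrt(a) -> Tensor:
    return pow_const(a, 0.5)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)

    def backward(g):
        return ((a, g * out),)

    return _node(out, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    out = np.log(a.data)

    def backward(g):
        return ((a, g / a.data),)

    return _node(out, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient is zero outside [lo, hi] (straight-through inside)."""
    a = as_tensor(a)
    out = np.clip(a.data, lo, hi)
    inside = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        return ((a, g * inside),)

    return _node(out, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out = np.maximum(a.data, 0.0)
    mask = a.data > 0

    def backward(g):
        return ((a, g * mask),)

    return _node(out, (a,), backward)


def leaky_relu(a, slope: float = 0.01) -> Tensor:
    a = as_tensor(a)
    coef = np.where(a.data > 0, 1.0, slope)
    out = a.data * coef

    def backward(g):
        return ((a, g * coef),)

    return _node(out, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        return ((a, g * out * (1.0 - out)),)

    return _node(out, (a,), backward)


# ---------------------------------------------------------------------------
# Linear algebra and reductions


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data

    def backward(g):
        return ((a, g @ b.data.T), (b, a.data.T @ g))

    return _node(out, (a, b), backward)


def spmm(S: sp.spmatrix, x) -> Tensor:
    """Constant sparse matrix times tensor: S @ X (gradient flows into X only)."""
    x = as_tensor(x)
    S = S.tocsr()
    out = S @ x.data
    ST = S.T.tocsr()

    def backward(g):
        return ((x, ST @ g),)

    return _node(out, (x,), backward)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return ((a, np.broadcast_to(g, a.shape).copy()),)

    return _node(out, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


# ---------------------------------------------------------------------------
# Indexed ops (message passing on edge lists)


def _scatter_add(idx: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    """Sum rows of ``values`` into ``n`` bins given by ``idx`` (column-wise
    bincount: much faster than np.add.at for many rows)."""
    if values.ndim == 1:
        return np.bincount(idx, weights=values, minlength=n)
    out = np.empty((n, values.shape[1]), dtype=np.float64)
    for j in range(values.shape[1]):
        out[:, j] = np.bincount(idx, weights=values[:, j], minlength=n)
    return out


def gather(a, idx: np.ndarray) -> Tensor:
    """Row gather: out[k] = a[idx[k]]; backward scatter-adds."""
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    out = a.data[idx]

    def backward(g):
        return ((a, _scatter_add(idx, g, a.data.shape[0]).reshape(a.shape)),)

    return _node(out, (a,), backward)


def segment_sum(a, idx: np.ndarray, n: int) -> Tensor:
    """out[k] = sum of rows a[e] with idx[e] == k, for k in 0..n-1."""
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    out = _scatter_add(idx, a.data, n)

    def backward(g):
        return ((a, g[idx]),)

    return _node(out, (a,), backward)


def segment_max_const(values: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Per-segment max of raw values (constant, used for softmax stabilization)."""
    out = np.full((n,) + values.shape[1:], -np.inf)
    np.maximum.at(out, np.asarray(idx, dtype=np.intp), values)
    return out


# ---------------------------------------------------------------------------
# Parameters and optimization


def parameter(data, rng: np.random.Generator | None = None, scale: float | None = None) -> Tensor:
    """Leaf tensor with gradient tracking; optionally random-normal initialized."""
    if rng is not None:
        shape = data if isinstance(data, tuple) else tuple(data)
        fan_in = shape[0] if shape else 1
        s = scale if scale is not None else 1.0 / np.sqrt(max(fan_in, 1))
        data = rng.normal(0.0, s, size=shape)
    return Tensor(np.asarray(data, dtype=np.float64).copy(), requires_grad=True)


class Adam:
    """Adam update rule with the standard moment decays.

    ``weight_decay`` is decoupled (AdamW-style) and applied only to
    parameters with 2 or more dimensions — weight matrices, not biases,
    gains or scalars.
    """

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * p.grad**2
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and p.data.ndim >= 2:
                p.data = p.data - self.lr * self.weight_decay * p.data


def finite_difference_grad(f: Callable[[np.ndarray], float], x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function; test oracle for gradients."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    flat = x.reshape(-1)
    gflat = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + h
        fp = f(x)
        flat[i] = orig - h
        fm = f(x)
        flat[i] = orig
        gflat[i] = (fp - fm) / (2.0 * h)
    return g
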