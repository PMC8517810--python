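"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ndarray; operations build a tape of closures that
``backward`` replays in reverse topological order. Only the operations the
package's models need are implemented; heavyweight layers (convolution,
batch norm, LSTM) register single fused nodes with hand-written backward
passes, which keeps the tape short and fast. Gradient correctness is pinned
by central-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def value(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def accumulate(t: Tensor, grad: np.ndarray) -> None:
    if not (isinstance(t, Tensor) and t.requires_grad):
        return
    grad = _unbroadcast(np.asarray(grad), t.data.shape)
    t.grad = grad if t.grad is None else t.grad + grad


def node(data: np.ndarray, parents, backward) -> Tensor:
    """Create a graph node. ``backward(grad_out)`` must call ``accumulate``."""
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = parents
        out._backward = backward
    return out


# -- elementwise / linear-algebra primitives -------------------------------


def add(a, b) -> Tensor:
    av, bv = value(a), value(b)
    out_parents = [x for x in (a, b) if isinstance(x, Tensor)]

    def backward(g):
        if isinstance(a, Tensor):
            accumulate(a, g)
        if isinstance(b, Tensor):
            accumulate(b, g)

    return node(av + bv, out_parents, backward)


def mul(a, b) -> Tensor:
    av, bv = value(a), value(b)

    def backward(g):
        if isinstance(a, Tensor):
            accumulate(a, g * bv)
        if isinstance(b, Tensor):
            accumulate(b, g * av)

    return node(av * bv, [a, b], backward)


def matmul(a, b) -> Tensor:
    av, bv = value(a), value(b)

    def backward(g):
        if isinstance(a, Tensor):
            accumulate(a, g @ bv.T)
        if isinstance(b, Tensor):
            accumulate(b, av.T @ g)

    return node(av @ bv, [a, b], backward)


def relu(x) -> Tensor:
    xv = value(x)
    mask = xv > 0

    def backward(g):
        accumulate(x, g * mask)

    return node(np.where(mask, xv, 0.0), [x], backward)


def sigmoid(x) -> Tensor:
    s = _sigmoid(value(x))

    def backward(g):
        accumulate(x, g * s * (1.0 - s))

    return node(s, [x], backward)


def softplus(x) -> Tensor:
    xv = value(x)

    def backward(g):
        accumulate(x, g * _sigmoid(xv))

    return node(np.logaddexp(0.0, xv), [x], backward)


def mean(x) -> Tensor:
    xv = value(x)

    def backward(g):
        accumulate(x, np.full_like(xv, g / xv.size))

    return node(np.asarray(xv.mean()), [x], backward)


def reshape(x, shape) -> Tensor:
    xv = value(x)

    def backward(g):
        accumulate(x, g.reshape(xv.shape))

    return node(xv.reshape(shape), [x], backward)


def concat(parts, axis: int = -1) -> Tensor:
    vals = [value(p) for p in parts]
    sizes = [v.shape[axis] for v in vals]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for p, gpart in zip(parts, np.split(g, splits, axis=axis)):
            if isinstance(p, Tensor):
                accumulate(p, gpart)

    return node(np.concatenate(vals, axis=axis), list(parts), backward)


def select_time(x, t: int) -> Tensor:
    """x[:, t, :] for a (N, T, H) tensor."""
    xv = value(x)

    def backward(g):
        gx = np.zeros_like(xv)
        gx[:, t, :] = g
        accumulate(x, gx)

    return node(xv[:, t, :], [x], backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
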