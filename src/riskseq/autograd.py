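"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical substrate for the recurrent models in
:mod:`riskseq.models`: a small define-by-run tape with the handful of
operations an LSTM/attention classifier needs (affine maps, pointwise
nonlinearities, embedding-bag gather/scatter, masked reductions, softmax).
Gradients are accumulated by reverse topological traversal of the tape.

Correctness is enforced by finite-difference checks in the test suite
rather than by construction; keep every ``backward`` closure a pure
function of the forward inputs.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["Tensor", "Adam", "sigmoid", "softmax_last", "embedding_bag", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node on the autodiff tape.

    ``requires_grad`` nodes accumulate into ``.grad`` on :meth:`backward`.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph plumbing ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _child(self, data: np.ndarray, parents: tuple["Tensor", ...]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) node with seed 1."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node._accum(g)
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                if parent._backward is None and parent._parents == ():
                    parent._accum(pg)
                else:
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = self._child(self.data + other.data, (self, other))
        if out.requires_grad:
            a, b = self, other
            out._backward = lambda g: (
                (a, _unbroadcast(g, a.data.shape)),
                (b, _unbroadcast(g, b.data.shape)),
            )
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._child(-self.data, (self,))
        if out.requires_grad:
            a = self
            out._backward = lambda g: ((a, -g),)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = self._child(self.data * other.data, (self, other))
        if out.requires_grad:
            a, b = self, other
            out._backward = lambda g: (
                (a, _unbroadcast(g * b.data, a.data.shape)),
                (b, _unbroadcast(g * a.data, b.data.shape)),
            )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = self._child(self.data / other.data, (self, other))
        if out.requires_grad:
            a, b = self, other
            out._backward = lambda g: (
                (a, _unbroadcast(g / b.data, a.data.shape)),
                (b, _unbroadcast(-g * a.data / b.data**2, b.data.shape)),
            )
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = self._child(self.data @ other.data, (self, other))
        if out.requires_grad:
            a, b = self, other
            out._backward = lambda g: (
                (a, g @ b.data.swapaxes(-1, -2)),
                (b, _unbroadcast(a.data.swapaxes(-1, -2) @ g, b.data.shape)),
            )
        return out

    __matmul__ = matmul

    # -- nonlinearities ------------------------------------------------
    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = self._child(y, (self,))
        if out.requires_grad:
            a = self
            out._backward = lambda g: ((a, g * (1.0 - y * y)),)
        return out

    def sigmoid(self) -> "Tensor":
        y = _sigmoid_np(self.data)
        out = self._child(y, (self,))
        if out.requires_grad:
            a = self
            out._backward = lambda g: ((a, g * y * (1.0 - y)),)
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = self._child(y, (self,))
        if out.requires_grad:
            a = self
            out._backward = lambda g: ((a, g * y),)
        return out

    def log(self) -> "Tensor":
        out = self._child(np.log(self.data), (self,))
        if out.requires_grad:
            a = self
            out._backward = lambda g: ((a, g / a.data),)
        return out

    # -- reductions / reshaping ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self._child(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            a = self

            def _bw(g, axis=axis, keepdims=keepdims):
                if axis is None:
                    return ((a, np.broadcast_to(g, a.data.shape).copy()),)
                gg = g if keepdims else np.expand_dims(g, axis)
                return ((a, np.broadcast_to(gg, a.data.shape).copy()),)

            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out = self._child(self.data.reshape(*shape), (self,))
        if out.requires_grad:
            a = self
            out._backward = lambda g: ((a, g.reshape(a.data.shape)),)
        return out

    def slice_last(self, start: int, stop: int) -> "Tensor":
        """Slice along the last axis (used to split fused gate matmuls)."""
        out = self._child(self.data[..., start:stop], (self,))
        if out.requires_grad:
            a = self

            def _bw(g, start=start, stop=stop):
                full = np.zeros_like(a.data)
                full[..., start:stop] = g
                return ((a, full),)

            out._backward = _bw
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _sigmoid_np(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _bw(g, axis=axis, splits=splits, tensors=tuple(tensors)):
            pieces = np.split(g, splits, axis=axis)
            return tuple(zip(tensors, pieces))

        out._backward = _bw
    return out


def softmax_last(x: Tensor, mask: np.ndarray | None = None) -> Tensor:
    """Softmax along the last axis; ``mask`` (0/1) marks valid positions.

    Masked-out positions receive exactly zero weight.
    """
    z = x.data
    if mask is not None:
        z = np.where(mask > 0, z, -np.inf)
    zmax = np.max(z, axis=-1, keepdims=True)
    e = np.exp(z - zmax)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y)
    out.requires_grad = x.requires_grad
    if out.requires_grad:
        out._parents = (x,)

        def _bw(g):
            dot = (g * y).sum(axis=-1, keepdims=True)
            return ((x, y * (g - dot)),)

        out._backward = _bw
    return out


def embedding_bag(table: Tensor, token_ids: np.ndarray, offsets: np.ndarray,
                  out_shape: tuple[int, ...]) -> Tensor:
    """Sum embedding rows per bag.

    ``token_ids`` is a flat int array; bag ``k`` owns the slice
    ``token_ids[offsets[k]:offsets[k+1]]`` (``offsets`` has one trailing
    sentinel). Returns bags reshaped to ``out_shape + (dim,)``; empty bags
    yield zero vectors.
    """
    dim = table.data.shape[1]
    nbags = len(offsets) - 1
    bags = np.zeros((nbags, dim))
    if len(token_ids):
        np.add.at(bags, np.repeat(np.arange(nbags), np.diff(offsets)), table.data[token_ids])
    out = Tensor(bags.reshape(out_shape + (dim,)))
    out.requires_grad = table.requires_grad
    if out.requires_grad:
        out._parents = (table,)

        def _bw(g):
            gflat = g.reshape(nbags, dim)
            gt = np.zeros_like(table.data)
            if len(token_ids):
                np.add.at(gt, token_ids, gflat[np.repeat(np.arange(nbags), np.diff(offsets))])
            return ((table, gt),)

        out._backward = _bw
    return out


class Adam:
    """Adam optimizer over a dict of named parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay:
                # decoupled decay: noise-driven weights shrink toward zero
                p.data *= 1.0 - self.lr * self.weight_decay
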