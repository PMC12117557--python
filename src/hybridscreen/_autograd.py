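"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the graph encoders and the MLP head need:
dense linear algebra, elementwise nonlinearities, row gather/scatter for
message passing, and segment reductions for graph readout.  Everything runs
in float64 with deterministic reduction order, so identical seeds give
bit-identical training runs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


class Tensor:
    """A node in the computation tape.

    Wraps an ndarray; ``backward()`` on a scalar Tensor accumulates
    gradients into every upstream Tensor with ``requires_grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
        """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
        if grad.shape == shape:
            return grad
        extra = grad.ndim - len(shape)
        if extra > 0:
            grad = grad.sum(axis=tuple(range(extra)))
        axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
        if axes:
            grad = grad.sum(axis=axes, keepdims=True)
        return grad

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (
                self._unbroadcast(g, self.data.shape),
                self._unbroadcast(g, other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data
        a, b = self.data, other.data

        def backward(g):
            return (
                self._unbroadcast(g * b, a.shape),
                self._unbroadcast(g * a, b.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data

        def backward(g):
            return (g @ b.T, a.T @ g)

        return self._make(a @ b, (self, other), backward)

    # -- nonlinearities -------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            return (g * s * (1.0 - s),)

        return self._make(s, (self,), backward)

    def shifted_softplus(self):
        """ssp(x) = ln(0.5 e^x + 0.5) = softplus(x) - ln 2; ssp(0) = 0."""
        x = self.data
        out = np.logaddexp(0.0, x) - np.log(2.0)
        sig = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))

        def backward(g):
            return (g * sig,)

        return self._make(out, (self,), backward)

    def log(self):
        x = self.data

        def backward(g):
            return (g / x,)

        return self._make(np.log(x), (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clip values; gradient passes through only inside the bounds."""
        inside = (self.data > lo) & (self.data < hi)

        def backward(g):
            return (g * inside,)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- structural ops -------------------------------------------------------

    def gather_rows(self, index: np.ndarray):
        index = np.asarray(index, dtype=np.intp)
        n_rows = self.data.shape[0]

        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, index, g)
            return (out,)

        return self._make(self.data[index], (self,), backward)

    def scatter_add_rows(self, index: np.ndarray, n_rows: int):
        """out[index[k]] += self[k]; the adjoint of gather_rows."""
        index = np.asarray(index, dtype=np.intp)
        out_data = np.zeros((n_rows,) + self.data.shape[1:], dtype=np.float64)
        np.add.at(out_data, index, self.data)

        def backward(g):
            return (g[index],)

        return self._make(out_data, (self,), backward)

    def segment_sum(self, segment_ids: np.ndarray, n_segments: int):
        return self.scatter_add_rows(segment_ids, n_segments)

    def segment_mean(self, segment_ids: np.ndarray, n_segments: int):
        segment_ids = np.asarray(segment_ids, dtype=np.intp)
        counts = np.bincount(segment_ids, minlength=n_segments).astype(np.float64)
        counts = np.maximum(counts, 1.0)
        summed = self.segment_sum(segment_ids, n_segments)
        return summed * Tensor(1.0 / counts[:, None] if self.data.ndim > 1 else 1.0 / counts)

    def concat(self, other, axis: int = 1):
        other = self._wrap(other)
        n = self.data.shape[axis]

        def backward(g):
            ga, gb = np.split(g, [n], axis=axis)
            return (ga, gb)

        return self._make(
            np.concatenate([self.data, other.data], axis=axis), (self, other), backward
        )

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            return (g.reshape(old),)

        return self._make(self.data.reshape(*shape), (self,), backward)

    def sum(self):
        shape = self.data.shape

        def backward(g):
            return (np.broadcast_to(g, shape).copy(),)

        return self._make(self.data.sum(), (self,), backward)

    def mean(self):
        n = self.data.size
        return self.sum() * (1.0 / n)

    # -- backprop -------------------------------------------------------------

    def backward(self):
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; training graphs can be deep
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

        grads: dict[int, np.ndarray] = {id(self): np.ones((), dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                parent_grads = node._backward(g)
                for parent, pg in zip(node._parents, parent_grads):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            else:  # leaf
                node.grad = g if node.grad is None else node.grad + g


def Parameter(data) -> Tensor:
    """A trainable leaf tensor."""
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)
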