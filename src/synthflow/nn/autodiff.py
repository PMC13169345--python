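"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied
to it; :meth:`Tensor.backward` walks the tape in reverse topological order
and accumulates gradients.  Only the operations needed by the models in
this package are implemented (dense algebra, softmax/log-softmax,
gather/scatter, reductions, element-wise nonlinearities).

Gradient computation can be disabled wholesale with :func:`no_grad`,
which turns every forward pass into plain NumPy (used for sampling and
beam search, where no tape is wanted).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling tape construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus the closure computing its parents' gradients."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # ------------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: tapes can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data * other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        out_data = self.data ** p
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def bw(g):
            self._accum(g * p * self.data ** (p - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data @ other.data
        req = self.requires_grad or other.requires_grad
        if not (req and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        src_shape = self.data.shape

        def bw(g):
            self._accum(g.reshape(src_shape))

        out._backward = bw
        return out

    def transpose(self, *axes) -> "Tensor":
        out_data = np.transpose(self.data, axes or None)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        inv = np.argsort(axes) if axes else None

        def bw(g):
            self._accum(np.transpose(g, inv))

        out._backward = bw
        return out

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        shape = self.data.shape

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- element-wise --------------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def bw(g):
            self._accum(g * out_data)

        out._backward = bw
        return out

    def log(self) -> "Tensor":
        out_data = np.log(self.data)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def bw(g):
            self._accum(g / self.data)

        out._backward = bw
        return out

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        out._backward = bw
        return out

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def bw(g):
            self._accum(g * (1.0 - out_data ** 2))

        out._backward = bw
        return out

    def sqrt(self) -> "Tensor":
        return self ** 0.5


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    """A leaf tensor tracked by optimizers."""
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


# ----------------------------------------------------------------------
# composite ops
# ----------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)
    out = Tensor(out_data, True, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)
    out = Tensor(out_data, True, tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = bw
    return out


def log_softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Numerically stable log-softmax; ``mask`` (boolean, True = keep)
    assigns masked-out entries probability 0 (log-prob -inf is avoided by
    a large negative constant held out of the tape)."""
    z = x
    if mask is not None:
        penalty = np.where(mask, 0.0, -1e9)
        z = z + Tensor(penalty)
    m = np.max(z.data, axis=axis, keepdims=True)  # constant shift
    shifted = z - Tensor(m)
    lse = shifted.exp().sum(axis=axis, keepdims=True).log()
    return shifted - lse


def softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    return log_softmax(x, axis=axis, mask=mask).exp()


def gather_last(x: Tensor, index: np.ndarray) -> Tensor:
    """Pick ``x[..., index]`` element-wise along the last axis
    (``index`` has x.shape[:-1])."""
    idx = tuple(np.indices(index.shape)) + (index,)
    return x[idx]


def scatter_rows(values: Tensor, index: np.ndarray, size: int) -> Tensor:
    """Place a 1-D ``values`` tensor into a zero vector of length ``size``
    at positions ``index`` (used to merge active-trajectory steps back
    into a fixed-size batch)."""
    out_data = np.zeros(size, dtype=np.float64)
    out_data[index] = values.data
    if not (values.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)
    out = Tensor(out_data, True, (values,))

    def bw(g):
        values._accum(g[index])

    out._backward = bw
    return out
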