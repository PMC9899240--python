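"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The embedding model in this package is a small masked-attention encoder
trained with a contrastive objective.  Rather than hand-deriving the
backward pass of every architectural variant, the model is expressed in a
tiny define-by-run autodiff layer: a :class:`Tensor` wraps a NumPy array
and records the operations applied to it; :meth:`Tensor.backward` walks the
recorded graph in reverse topological order and accumulates gradients.

Only the primitives the model needs are provided (broadcast arithmetic,
batched matmul, masked softmax, layer normalisation, log-softmax, indexing,
concatenation, reductions).  Gradients are accumulated on every node, which
the interpretability module exploits to read attention-matrix gradients.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "no_grad", "concat", "Adam", "set_dtype", "get_dtype"]

_grad_enabled = True

# Model training is memory-bandwidth bound; single precision is the default.
# Tests of analytic gradients switch to float64 via set_dtype.
_dtype = np.float32


def set_dtype(dtype) -> None:
    """Set the global array dtype for newly created Tensors."""
    global _dtype
    _dtype = np.dtype(dtype).type


def get_dtype():
    return _dtype


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the context (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast from `shape`."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """NumPy array with gradient tracking."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_dtype)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an argument needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray, own: bool = False) -> None:
        # `own=True` promises `grad` is freshly allocated and unshared, so it
        # can be adopted without a defensive copy.
        if self.grad is None:
            self.grad = grad if own else grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- basic properties --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                ga = _unbroadcast(g, self.data.shape)
                self._accum(ga, own=ga is not g)
            if other.requires_grad:
                gb = _unbroadcast(g, other.data.shape)
                other._accum(gb, own=gb is not g)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g, own=True)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape), own=True)
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape), own=True)

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape), own=True)
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape), own=True)

        return Tensor._make(out_data, (self, other), backward)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1), own=True)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        a, b = self.data, other.data
        out_data = a @ b

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(b, -1, -2)
                self._accum(_unbroadcast(ga, a.shape), own=True)
            if other.requires_grad:
                gb = np.swapaxes(a, -1, -2) @ g
                other._accum(_unbroadcast(gb, b.shape), own=True)

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities ----------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask, own=True)

        return Tensor._make(self.data * mask, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2), own=True)

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data, own=True)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data, own=True)

        return Tensor._make(np.log(self.data), (self,), backward)

    # -- shape manipulation --------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        advanced = any(
            isinstance(i, (np.ndarray, list)) for i in (idx if isinstance(idx, tuple) else (idx,))
        )

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if advanced:
                    np.add.at(full, idx, g)
                else:
                    full[idx] += g
                self._accum(full, own=True)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy(), own=True)
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy(), own=True)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- composite primitives with bespoke backward ---------------------------
    def masked_softmax(self, mask: np.ndarray):
        """Softmax over the last axis restricted to entries where `mask` is True.

        Disallowed entries get probability exactly 0; rows with no allowed
        entry come out as all zeros.  `mask` broadcasts against the data.
        """
        mask_b = np.broadcast_to(mask, self.data.shape)
        lowest = np.asarray(-1e30, dtype=self.data.dtype)
        scores = np.where(mask_b, self.data, lowest)
        scores -= scores.max(axis=-1, keepdims=True)
        with np.errstate(under="ignore"):
            np.exp(scores, out=scores)  # masked entries underflow to exactly 0
        scores /= scores.sum(axis=-1, keepdims=True)
        probs = scores * mask_b  # all-masked rows become exact zeros

        def backward(g):
            if self.requires_grad:
                inner = (g * probs).sum(axis=-1, keepdims=True)
                self._accum(probs * (g - inner), own=True)

        return Tensor._make(probs, (self,), backward)

    def masked_softmax_additive(self, additive: np.ndarray):
        """Softmax over the last axis after adding a 0 / -1e30 mask array.

        Equivalent to :meth:`masked_softmax` with ``mask = additive == 0``
        but cheaper: forbidden entries underflow to probability exactly 0.
        """
        scores = self.data + additive
        scores -= scores.max(axis=-1, keepdims=True)
        with np.errstate(under="ignore"):
            np.exp(scores, out=scores)
        scores /= scores.sum(axis=-1, keepdims=True)
        probs = scores

        def backward(g):
            if self.requires_grad:
                inner = (g * probs).sum(axis=-1, keepdims=True)
                self._accum(probs * (g - inner), own=True)

        return Tensor._make(probs, (self,), backward)

    def log_softmax(self):
        """Log-softmax over the last axis (numerically stable)."""
        shifted = self.data - self.data.max(axis=-1, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
        out_data = shifted - lse
        softmax = np.exp(out_data)

        def backward(g):
            if self.requires_grad:
                self._accum(g - softmax * g.sum(axis=-1, keepdims=True), own=True)

        return Tensor._make(out_data, (self,), backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalise over the last axis, then scale and shift."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out_data = xhat * gamma.data + beta.data
        n = x.shape[-1]

        def backward(g):
            if gamma.requires_grad:
                gamma._accum(_unbroadcast(g * xhat, gamma.data.shape), own=True)
            if beta.requires_grad:
                gb = _unbroadcast(g, beta.data.shape)
                beta._accum(gb, own=gb is not g)
            if self.requires_grad:
                dxhat = g * gamma.data
                term = n * dxhat - dxhat.sum(axis=-1, keepdims=True)
                term -= xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
                self._accum(inv / n * term, own=True)

        return Tensor._make(out_data, (self, gamma, beta), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis`."""
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tensors, backward)


class Adam:
    """Adam optimiser over a dict of parameter Tensors (default hyperparameters)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            m = self._m[k]
            v = self._v[k]
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
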