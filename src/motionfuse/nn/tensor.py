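"""Reverse-mode automatic differentiation on numpy arrays.

A minimal define-by-run tape: every operation on :class:`Tensor` records a
closure that propagates the upstream gradient to its parents.  Gradients are
accumulated in ``.grad`` (a plain ndarray) after calling :meth:`Tensor.backward`
on a scalar loss.  Broadcasting follows numpy semantics; the backward pass
sums gradients over broadcast axes.

Only the primitives the model needs are implemented.  Everything is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack", "where", "logsumexp",
           "softplus", "erf", "no_grad", "is_grad_enabled",
           "set_default_dtype", "get_default_dtype", "autodiff_dtype"]

_GRAD_ENABLED = True
_DTYPE = np.float32     # single precision: the standard deep-learning choice


def set_default_dtype(dtype):
    """Set the floating dtype new tensors are cast to (float32/float64)."""
    global _DTYPE
    _DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return _DTYPE


class autodiff_dtype:
    """Context manager pinning the tensor dtype (e.g. float64 for
    finite-difference gradient checks)."""

    def __init__(self, dtype):
        self.dtype = dtype

    def __enter__(self):
        self._prev = _DTYPE
        set_default_dtype(self.dtype)

    def __exit__(self, *exc):
        set_default_dtype(self._prev)
        return False


class no_grad:
    """Context manager: ops executed inside build no autodiff graph."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=_DTYPE)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None,
                 name: str | None = None):
        self.data = data if isinstance(data, np.ndarray) else _as_array(data)
        if self.data.dtype != _DTYPE:
            self.data = self.data.astype(_DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        if _GRAD_ENABLED:
            self._prev = tuple(p for p in _prev if p.requires_grad or p._prev)
        else:
            self._prev = ()
        self._backward = _backward
        self.name = name

    # -- basic protocol -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph machinery ----------------------------------------------------
    def _accum(self, g: np.ndarray, owned: bool = False):
        # ``owned=True`` promises g is a fresh array (or a view of a grad
        # buffer that is already final), so it can be adopted without copy.
        # g may also be broadcast-shaped (reduction backward).
        if self.grad is None:
            if np.shape(g) == self.data.shape:
                self.grad = g if owned else np.array(g)
            else:
                self.grad = np.zeros_like(self.data)
                self.grad += g
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs from RNN loops can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accum(-g, owned=True)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g * other.data, self.data.shape),
                            owned=True)
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(g * self.data, other.data.shape),
                             owned=True)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g / other.data, self.data.shape),
                            owned=True)
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.data.shape), owned=True)
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1), owned=True)
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), _prev=(self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape), owned=True)
            if other.requires_grad or other._prev:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape), owned=True)
        out._backward = bw
        return out

    # -- elementwise nonlinearities ----------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g * out.data, owned=True)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g / self.data, owned=True)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data ** 2), owned=True)
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _prev=(self,))
        out._backward = lambda g: self._accum(g * out.data * (1.0 - out.data), owned=True)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0), owned=True)
        return out

    def sqrt(self):
        return self ** 0.5

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(g)      # broadcasting add, no materialized copy
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda g: self._accum(g.reshape(orig), owned=True)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv), owned=True)
        return out

    def swapaxes(self, a, b):
        out = Tensor(np.swapaxes(self.data, a, b), _prev=(self,))
        out._backward = lambda g: self._accum(np.swapaxes(g, a, b), owned=True)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))
        # basic indexing (ints/slices) never repeats elements, so the
        # scatter can be a plain in-place add into the shared grad buffer;
        # advanced (array) indexing needs unbuffered np.add.at
        parts = idx if isinstance(idx, tuple) else (idx,)
        fancy = any(isinstance(p, (np.ndarray, list)) for p in parts)

        def bw(g):
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            if fancy:
                np.add.at(self.grad, idx, g)
            else:
                self.grad[idx] += g
        out._backward = bw
        return out

    def pad(self, pad_width):
        """Zero padding; ``pad_width`` as for :func:`numpy.pad`."""
        out = Tensor(np.pad(self.data, pad_width), _prev=(self,))
        slices = tuple(slice(b, s + b) for (b, _), s
                       in zip(pad_width, self.data.shape))
        out._backward = lambda g: self._accum(g[slices], owned=True)
        return out


# -- free functions ---------------------------------------------------------

def concatenate(tensors, axis=0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._prev:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)], owned=True)
    out._backward = bw
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))

    def bw(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad or t._prev:
                t._accum(np.squeeze(p, axis=axis), owned=True)
    out._backward = bw
    return out


def where(cond: np.ndarray, a, b) -> Tensor:
    a, b = Tensor._lift(a), Tensor._lift(b)
    out = Tensor(np.where(cond, a.data, b.data), _prev=(a, b))

    def bw(g):
        if a.requires_grad or a._prev:
            a._accum(_unbroadcast(np.where(cond, g, 0.0), a.data.shape), owned=True)
        if b.requires_grad or b._prev:
            b._accum(_unbroadcast(np.where(cond, 0.0, g), b.data.shape), owned=True)
    out._backward = bw
    return out


def logsumexp(x: Tensor, axis=-1, keepdims=False) -> Tensor:
    """Numerically stable log-sum-exp; gradient is the softmax."""
    m = x.data.max(axis=axis, keepdims=True)
    val = np.log(np.exp(x.data - m).sum(axis=axis, keepdims=True)) + m
    out_data = val if keepdims else np.squeeze(val, axis=axis)
    out = Tensor(out_data, _prev=(x,))
    sm = np.exp(x.data - val)  # softmax along axis

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accum(g * sm, owned=True)
    out._backward = bw
    return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), overflow-safe; gradient sigmoid(x)."""
    out = Tensor(np.logaddexp(0.0, x.data), _prev=(x,))
    sig = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    out._backward = lambda g: x._accum(g * sig, owned=True)
    return out


def erf(x: Tensor) -> Tensor:
    from scipy.special import erf as _erf
    out = Tensor(_erf(x.data), _prev=(x,))
    c = 2.0 / np.sqrt(np.pi)
    out._backward = lambda g: x._accum(g * c * np.exp(-x.data ** 2), owned=True)
    return out
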