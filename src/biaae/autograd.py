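"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape; :meth:`Tensor.backward` replays the tape in reverse to
accumulate gradients into every reachable leaf with ``requires_grad=True``.
Only the operations the models in this package need are implemented —
broadcasting elementwise arithmetic, matmul, reductions, concatenation,
slicing, the usual activations and a categorical cross-entropy primitive.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "no_grad"]


def _as_array(value) -> np.ndarray:
    if isinstance(value, Tensor):
        raise TypeError("expected raw array-like, got Tensor")
    return np.asarray(value, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class _NoGrad:
    _depth = 0

    def __enter__(self):
        _NoGrad._depth += 1
        return self

    def __exit__(self, *exc):
        _NoGrad._depth -= 1
        return False

    @classmethod
    def active(cls) -> bool:
        return cls._depth > 0


def no_grad() -> _NoGrad:
    """Context manager suppressing tape construction (inference mode)."""
    return _NoGrad()


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers to Tensor in mixed ops

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and not _NoGrad.active()
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents, backward) -> "Tensor":
        out = Tensor(data)
        if not _NoGrad.active() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(grad):
            return (_unbroadcast(grad, self.shape), _unbroadcast(grad, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(grad):
            return (
                _unbroadcast(grad * other.data, self.shape),
                _unbroadcast(grad * self.data, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def backward(grad):
            return (
                _unbroadcast(grad / other.data, self.shape),
                _unbroadcast(-grad * self.data / other.data**2, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(grad):
            return (grad * exponent * self.data ** (exponent - 1),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward(grad):
            return (grad @ other.data.T, self.data.T @ grad)

        return Tensor._make(out_data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        out_data = self.data.reshape(*shape)

        def backward(grad):
            return (grad.reshape(orig),)

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, index):
        out_data = self.data[index]

        def backward(grad):
            full = np.zeros_like(self.data)
            np.add.at(full, index, grad)
            return (full,)

        return Tensor._make(out_data, (self,), backward)

    @property
    def T(self):
        out_data = self.data.T

        def backward(grad):
            return (grad.T,)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad):
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / count

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(grad):
            g = np.asarray(grad)
            out = out_data
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
                out = np.expand_dims(out_data, axis)
            mask = self.data == out
            mask = mask / mask.sum(axis=axis, keepdims=True) if axis is not None else mask / mask.sum()
            return (mask * g,)

        return Tensor._make(out_data, (self,), backward)

    # -- elementwise nonlinearities --------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        def backward(grad):
            return (grad / self.data,)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * (1.0 - out_data**2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    def log_sigmoid(self):
        """Numerically stable log σ(x) = −softplus(−x); gradient σ(−x)."""
        from scipy.special import expit

        x = self.data
        out_data = np.minimum(x, 0.0) - np.log1p(np.exp(-np.abs(x)))
        sig_neg = expit(-x)

        def backward(grad):
            return (grad * sig_neg,)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)
        return Tensor._make(self.data * factor, (self,), lambda g: (g * factor,))

    def clamp_min(self, low: float):
        mask = self.data >= low
        return Tensor._make(np.maximum(self.data, low), (self,), lambda g: (g * mask,))

    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        logits = shifted - np.log(np.exp(shifted).sum(axis=axis, keepdims=True))

        def backward(grad):
            softmax = np.exp(logits)
            return (grad - softmax * grad.sum(axis=axis, keepdims=True),)

        return Tensor._make(logits, (self,), backward)

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order of the tape
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            node_grad = grads.pop(id(node), None)
            if node_grad is None:
                continue
            if node._backward is None:  # leaf
                node.grad = node_grad if node.grad is None else node.grad + node_grad
                continue
            for parent, parent_grad in zip(node._parents, node._backward(node_grad)):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = parent_grad if key not in grads else grads[key] + parent_grad


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad):
        return tuple(np.split(grad, splits, axis=axis))

    return Tensor._make(out_data, tensors, backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(grad):
        return tuple(np.moveaxis(grad, axis, 0))

    return Tensor._make(out_data, tensors, backward)
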