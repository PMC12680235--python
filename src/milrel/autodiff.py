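"""Minimal reverse-mode automatic differentiation on numpy arrays.

The MIL aggregators in this package are small (a linear feature compressor,
gated-attention blocks and linear classifiers), so a compact tape-based
autodiff engine over dense float64 arrays is sufficient to train them with
Adam on CPU. Gradients are exercised against central finite differences in
the test suite.

Only the primitives the models need are implemented: broadcasting
arithmetic, matmul, the usual pointwise nonlinearities, reductions
(sum / mean / max), softmax / log-softmax, concatenation and slicing.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "cross_entropy", "concat", "stack",
           "set_default_dtype", "get_default_dtype"]

# Single precision is the default, as is conventional for neural-network
# training; switch to float64 for finite-difference gradient checks.
_DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global _DTYPE
    if np.dtype(dtype) not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    _DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return _DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        data = self.data + other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        data = self.data * other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        data = self.data ** p

        def backward(g: np.ndarray) -> None:
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(data, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        data = self.data @ other.data

        def backward(g: np.ndarray) -> None:
            a, b = self.data, other.data
            if self.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    self._accum(g * b)
                elif a.ndim == 2 and b.ndim == 1:
                    self._accum(np.outer(g, b))
                elif a.ndim == 1 and b.ndim == 2:
                    self._accum(b @ g)
                else:
                    self._accum(g @ b.T)
            if other.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    other._accum(g * a)
                elif a.ndim == 2 and b.ndim == 1:
                    other._accum(a.T @ g)
                elif a.ndim == 1 and b.ndim == 2:
                    other._accum(np.outer(a, g))
                else:
                    other._accum(a.T @ g)

        return Tensor._make(data, (self, other), backward)

    # -- pointwise nonlinearities --------------------------------------------

    def relu(self) -> "Tensor":
        data = np.maximum(self.data, 0.0)

        def backward(g: np.ndarray) -> None:
            self._accum(g * (self.data > 0))

        return Tensor._make(data, (self,), backward)

    def tanh(self) -> "Tensor":
        data = np.tanh(self.data)

        def backward(g: np.ndarray) -> None:
            self._accum(g * (1.0 - data ** 2))

        return Tensor._make(data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g: np.ndarray) -> None:
            self._accum(g * data * (1.0 - data))

        return Tensor._make(data, (self,), backward)

    def exp(self) -> "Tensor":
        data = np.exp(self.data)

        def backward(g: np.ndarray) -> None:
            self._accum(g * data)

        return Tensor._make(data, (self,), backward)

    def log(self) -> "Tensor":
        data = np.log(self.data)

        def backward(g: np.ndarray) -> None:
            self._accum(g / self.data)

        return Tensor._make(data, (self,), backward)

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: np.ndarray) -> None:
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int) -> "Tensor":
        """Max along `axis`; gradient routes to the first arg-max entry."""
        data = self.data.max(axis=axis)
        idx = self.data.argmax(axis=axis)

        def backward(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            grid = np.indices(data.shape)
            index = list(grid)
            index.insert(axis, idx)
            full[tuple(index)] = g
            self._accum(full)

        return Tensor._make(data, (self,), backward)

    # -- softmax family -------------------------------------------------------

    def log_softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        data = shifted - lse

        def backward(g: np.ndarray) -> None:
            sm = np.exp(data)
            self._accum(g - sm * g.sum(axis=axis, keepdims=True))

        return Tensor._make(data, (self,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        data = e / e.sum(axis=axis, keepdims=True)

        def backward(g: np.ndarray) -> None:
            dot = (g * data).sum(axis=axis, keepdims=True)
            self._accum(data * (g - dot))

        return Tensor._make(data, (self,), backward)

    # -- shaping --------------------------------------------------------------

    def __getitem__(self, key) -> "Tensor":
        data = self.data[key]

        def backward(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        return Tensor._make(data, (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        data = self.data.reshape(*shape)

        def backward(g: np.ndarray) -> None:
            self._accum(g.reshape(self.data.shape))

        return Tensor._make(data, (self,), backward)

    @property
    def T(self) -> "Tensor":
        data = self.data.T

        def backward(g: np.ndarray) -> None:
            self._accum(g.T)

        return Tensor._make(data, (self,), backward)

    # -- backward pass --------------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar output."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(data, tensors, backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g: np.ndarray) -> None:
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(data, tensors, backward)


def cross_entropy(logits: Tensor, label: int) -> Tensor:
    """Negative log-likelihood of `label` under softmax(logits) (1-D logits)."""
    return -logits.log_softmax(axis=-1)[int(label)]


class Adam:
    """Adam optimizer with decoupled-style L2 weight decay added to the gradient."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._scratch = [np.empty_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        # fold bias correction into scalar coefficients; update in place
        corr1 = 1 - self.b1 ** self.t
        corr2 = 1 - self.b2 ** self.t
        alpha = self.lr * np.sqrt(corr2) / corr1
        eps = self.eps * np.sqrt(corr2)
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                # fold L2 term into the gradient, reusing the grad buffer
                g += self.weight_decay * p.data
            m, v, t = self._m[i], self._v[i], self._scratch[i]
            m *= self.b1
            np.multiply(g, 1 - self.b1, out=t)
            m += t
            v *= self.b2
            np.multiply(g, g, out=t)
            t *= 1 - self.b2
            v += t
            np.sqrt(v, out=t)
            t += eps
            np.divide(m, t, out=t)
            t *= alpha
            p.data -= t
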