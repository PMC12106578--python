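"""Minimal reverse-mode automatic differentiation over numpy arrays.

The dynamic model trains by gradient descent through a recurrent computation
graph (a GRU evolving GCN weight matrices across an age axis, followed by a
pair-scoring MLP).  The graphs involved are tiny (tens of nodes, widths of a
few dozen), so a tape-based scalar-overhead engine on float64 numpy arrays is
both fast enough and easy to verify against finite differences.

Only the operations the model needs are provided: broadcast arithmetic,
matrix product, transpose, sigmoid/tanh/relu/softplus, sqrt, reductions,
row gather / zero-padding, and concatenation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "sigmoid",
    "tanh",
    "relu",
    "softplus",
    "sqrt",
    "matmul",
    "concat",
    "take_rows",
    "pad_rows",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A float64 array with optional gradient tracking."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    @property
    def ndim(self) -> int:
        return self.value.ndim

    def item(self) -> float:
        return float(self.value)

    def detach(self) -> "Tensor":
        return Tensor(self.value.copy())

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor to all leaves."""
        # Iterative post-order topological sort; recursion would overflow on
        # long recurrent chains (one GRU step per age per layer).
        order: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self._accumulate(np.ones_like(self.value))
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), Tensor(-1.0)))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, Tensor(-1.0)))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    @property
    def T(self) -> "Tensor":
        return transpose(self)

    def sum(self, axis=None):
        return tsum(self, axis=axis)

    def mean(self, axis=None):
        return tmean(self, axis=axis)

    def reshape(self, shape):
        return reshape(self, shape)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.shape}{flag})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(value) -> Tensor:
    return Tensor(value)


def parameter(value) -> Tensor:
    return Tensor(value, requires_grad=True)


def _make(value, parents, backward) -> Tensor:
    out = Tensor(value)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


# -- elementwise arithmetic ----------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    value = a.value + b.value

    def backward(grad):
        if a.requires_grad:
            a._accumulate(_unbroadcast(grad, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(grad, b.shape))

    return _make(value, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    value = a.value * b.value

    def backward(grad):
        if a.requires_grad:
            a._accumulate(_unbroadcast(grad * b.value, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(grad * a.value, b.shape))

    return _make(value, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    value = a.value / b.value

    def backward(grad):
        if a.requires_grad:
            a._accumulate(_unbroadcast(grad / b.value, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-grad * a.value / b.value**2, b.shape))

    return _make(value, (a, b), backward)


# -- linear algebra -------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    value = a.value @ b.value

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad @ b.value.T)
        if b.requires_grad:
            b._accumulate(a.value.T @ grad)

    return _make(value, (a, b), backward)


def transpose(a: Tensor) -> Tensor:
    value = a.value.T

    def backward(grad):
        a._accumulate(grad.T)

    return _make(value, (a,), backward)


# -- nonlinearities -------------------------------------------------------

def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    value = 0.5 * (1.0 + np.tanh(0.5 * a.value))  # numerically stable logistic

    def backward(grad):
        a._accumulate(grad * value * (1.0 - value))

    return _make(value, (a,), backward)


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    value = np.tanh(a.value)

    def backward(grad):
        a._accumulate(grad * (1.0 - value**2))

    return _make(value, (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    value = np.maximum(a.value, 0.0)

    def backward(grad):
        a._accumulate(grad * (a.value > 0.0))

    return _make(value, (a,), backward)


def softplus(a) -> Tensor:
    """log(1 + exp(x)), computed stably via logaddexp."""
    a = _as_tensor(a)
    value = np.logaddexp(0.0, a.value)

    def backward(grad):
        sig = 0.5 * (1.0 + np.tanh(0.5 * a.value))
        a._accumulate(grad * sig)

    return _make(value, (a,), backward)


def sqrt(a) -> Tensor:
    a = _as_tensor(a)
    value = np.sqrt(a.value)

    def backward(grad):
        a._accumulate(grad * 0.5 / value)

    return _make(value, (a,), backward)


# -- reductions and shape ops --------------------------------------------

def tsum(a: Tensor, axis=None) -> Tensor:
    value = a.value.sum(axis=axis)

    def backward(grad):
        if axis is None:
            a._accumulate(np.broadcast_to(grad, a.shape).astype(np.float64))
        else:
            a._accumulate(np.broadcast_to(np.expand_dims(grad, axis), a.shape).copy())

    return _make(value, (a,), backward)


def tmean(a: Tensor, axis=None) -> Tensor:
    n = a.value.size if axis is None else a.value.shape[axis]
    return mul(tsum(a, axis=axis), Tensor(1.0 / n))


def reshape(a: Tensor, shape) -> Tensor:
    old_shape = a.shape
    value = a.value.reshape(shape)

    def backward(grad):
        a._accumulate(grad.reshape(old_shape))

    return _make(value, (a,), backward)


def take_rows(a: Tensor, indices) -> Tensor:
    """Gather rows of a 2-D tensor (duplicate indices accumulate gradients)."""
    indices = np.asarray(indices, dtype=np.intp)
    value = a.value[indices]

    def backward(grad):
        full = np.zeros_like(a.value)
        np.add.at(full, indices, grad)
        a._accumulate(full)

    return _make(value, (a,), backward)


def pad_rows(a: Tensor, total_rows: int) -> Tensor:
    """Zero-pad a 2-D tensor at the bottom up to ``total_rows`` rows."""
    n, d = a.shape
    if total_rows < n:
        raise ValueError(f"cannot pad {n} rows down to {total_rows}")
    value = np.zeros((total_rows, d))
    value[:n] = a.value

    def backward(grad):
        a._accumulate(grad[:n])

    return _make(value, (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    value = np.concatenate([t.value for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * grad.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(grad[tuple(sl)])

    return _make(value, tuple(tensors), backward)


# -- optimizer ------------------------------------------------------------

class Adam:
    """Adam over a name -> Tensor parameter dict (all requires_grad)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, p in self.params.items():
            if p.grad is None:
                continue
            m = self._m[key] = b1 * self._m[key] + (1 - b1) * p.grad
            v = self._v[key] = b2 * self._v[key] + (1 - b2) * p.grad**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
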