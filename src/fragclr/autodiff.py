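"""A small reverse-mode automatic differentiation engine over NumPy arrays.

Supports exactly the operations the graph encoders, the set-Transformer fusion
and the contrastive losses need: elementwise arithmetic, matmul, exp/log/tanh/
sigmoid/relu/elu/leaky-relu, reductions, concatenation, row gather and
segment-sum scatter.  Everything runs in float64, so two runs with the same
seed are bitwise identical.

Gradients accumulate into ``Tensor.grad`` after calling :meth:`Tensor.backward`
on a scalar.  The graph is torn down implicitly when tensors go out of scope.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "stack_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: Sequence["Tensor"] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = tuple(p for p in _prev if p.requires_grad)
        self._backward = _backward

    # ---- construction helpers ----------------------------------------------

    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    @staticmethod
    def const(data) -> "Tensor":
        return Tensor(data, requires_grad=False)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    # ---- arithmetic ---------------------------------------------------------

    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor.const(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))
        a_vec = self.data.ndim == 1
        b_vec = other.data.ndim == 1

        def backward(g):
            if self.requires_grad:
                if b_vec:
                    self._accumulate(np.outer(g, other.data) if not a_vec
                                     else g * other.data)
                else:
                    self._accumulate(g @ other.data.T)
            if other.requires_grad:
                if a_vec:
                    other._accumulate(np.outer(self.data, g) if not b_vec
                                      else g * self.data)
                else:
                    other._accumulate(self.data.T @ g)

        out._backward = backward
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    # ---- nonlinearities -----------------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - out.data**2))
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * out.data * (1.0 - out.data))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0.0))
        return out

    def leaky_relu(self, alpha: float = 0.01):
        out = Tensor(np.where(self.data > 0, self.data, alpha * self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(
            g * np.where(self.data > 0, 1.0, alpha)
        )
        return out

    def elu(self, alpha: float = 1.0):
        out = Tensor(
            np.where(self.data > 0, self.data, alpha * (np.exp(self.data) - 1.0)),
            _prev=(self,),
        )
        out._backward = lambda g: self._accumulate(
            g * np.where(self.data > 0, 1.0, alpha * np.exp(np.minimum(self.data, 0.0)))
        )
        return out

    # ---- shape & reductions -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, _prev=(self,))
        out._backward = lambda g: self._accumulate(g.T)
        return out

    def gather(self, index: np.ndarray):
        """Select rows by integer index (with repetition)."""
        index = np.asarray(index, dtype=np.intp)
        out = Tensor(self.data[index], _prev=(self,))

        def backward(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, index, g)
            self._accumulate(acc)

        out._backward = backward
        return out

    def segment_sum(self, segment_ids: np.ndarray, num_segments: int):
        """Scatter-add rows into ``num_segments`` buckets."""
        segment_ids = np.asarray(segment_ids, dtype=np.intp)
        shape = (num_segments,) + self.data.shape[1:]
        acc = np.zeros(shape)
        np.add.at(acc, segment_ids, self.data)
        out = Tensor(acc, _prev=(self,))
        out._backward = lambda g: self._accumulate(g[segment_ids])
        return out

    def norm(self):
        """Euclidean norm of a vector (scalar output)."""
        return (self * self).sum() ** 0.5

    # ---- backprop -----------------------------------------------------------

    def backward(self) -> None:
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.array(1.0)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _prev=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = backward
    return out


def stack_rows(tensors: Sequence[Tensor]) -> Tensor:
    """Stack 1-D tensors into a 2-D matrix, one row each."""
    out = Tensor(np.stack([t.data for t in tensors]), _prev=tuple(tensors))

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(g[i])

    out._backward = backward
    return out


class Adam:
    """Adam optimiser over a name → Tensor parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
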