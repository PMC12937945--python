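"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the package's neural components need:
broadcast arithmetic, batched matmul, ReLU / leaky ReLU / sigmoid, log,
exp, power, reductions, reshape / transpose / concat / slicing, and a
numerically stable softmax.  Gradients for broadcast operations are
summed back to the parameter's shape.  Everything is deterministic given
the numpy arrays fed in; all randomness (init, dropout masks, batch
order) lives in the callers' seeded generators.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(_prev)

    # -- helpers -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _needs(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, self._needs(other), (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, self._needs(other), (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, self._needs(other), (self, other))
        # promote 1-D operands so the batched-gradient rule is uniform
        a2 = self.data[None, :] if self.ndim == 1 else self.data
        b2 = other.data[:, None] if other.ndim == 1 else other.data

        def backward(g):
            g2 = g
            if self.ndim == 1:
                g2 = np.expand_dims(g2, -2)
            if other.ndim == 1:
                g2 = np.expand_dims(g2, -1)
            if self.requires_grad:
                ga = g2 @ np.swapaxes(b2, -1, -2)
                if self.ndim == 1:
                    ga = ga.reshape(-1, self.shape[0]).sum(axis=0)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(a2, -1, -2) @ g2
                if other.ndim == 1:
                    gb = np.moveaxis(gb, -2, 0).reshape(other.shape[0], -1).sum(axis=1)
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = backward
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(
            np.where(self.data > 0, self.data, slope * self.data),
            self.requires_grad,
            (self,),
        )

        def backward(g):
            if self.requires_grad:
                self._accum(g * np.where(self.data > 0, 1.0, slope))

        out._backward = backward
        return out

    def sigmoid(self):
        s = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable logistic
        out = Tensor(s, self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = backward
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * e)

        out._backward = backward
        return out

    # -- reductions & shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        out._backward = backward
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))

        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = backward
        return out

    # -- autodiff driver ---------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
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
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))  # constant shift
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adaptive-moment stochastic optimizer over a list of Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)
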