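"""A minimal reverse-mode automatic-differentiation engine on numpy arrays.

Supports exactly the tensor operations the encoder and the contrastive losses
need: broadcast arithmetic, (batched) matmul, exp/log/tanh/pow, axis
reductions, reshape/swapaxes, embedding lookup, and elementwise selection via
constant masks. Everything is float64. Gradient correctness is verified
against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def backward():
            g = out.grad
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.expand_dims(g, -1) * other.data
                else:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.expand_dims(self.data, -1) * np.expand_dims(g, -2)
                else:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = backward
        return out

    # -- elementwise -------------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out.data)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = backward
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - out.data ** 2))

        out._backward = backward
        return out

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def backward():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out._backward = backward
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), _prev=(self,))

        def backward():
            if self.requires_grad:
                self._accum(np.swapaxes(out.grad, a, b))

        out._backward = backward
        return out

    @property
    def T(self):
        return self.swapaxes(-1, -2)


def free_graph(*tensors: Tensor) -> None:
    """Release a computation graph eagerly.

    Backward closures capture their output tensor, so every node sits in a
    reference cycle and would otherwise wait for the cyclic garbage
    collector — which does not see numpy buffer sizes and lets memory grow.
    Call this on the root(s) once a step's values/gradients have been used.
    Leaf tensors (parameters) keep their data; their grads are cleared.
    """
    stack, seen = list(tensors), set()
    while stack:
        t = stack.pop()
        if id(t) in seen:
            continue
        seen.add(id(t))
        stack.extend(t._prev)
        t._prev = ()
        t._backward = None
        t.grad = None


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))

    def backward():
        sizes = [t.data.shape[axis] for t in tensors]
        pieces = np.split(out.grad, np.cumsum(sizes)[:-1], axis=axis)
        for t, g in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(g)

    out._backward = backward
    return out


def take_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows along axis 0 (e.g. a batch permutation)."""
    idx = np.asarray(idx)
    out = Tensor(t.data[idx], _prev=(t,))

    def backward():
        if t.requires_grad:
            g = np.zeros_like(t.data)
            np.add.at(g, idx, out.grad)
            t._accum(g)

    out._backward = backward
    return out


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup `weight[ids]` with scatter-add gradient."""
    ids = np.asarray(ids)
    out = Tensor(weight.data[ids], _prev=(weight,))

    def backward():
        if weight.requires_grad:
            g = np.zeros_like(weight.data)
            np.add.at(g, ids.reshape(-1), out.grad.reshape(-1, weight.data.shape[-1]))
            weight._accum(g)

    out._backward = backward
    return out


def softmax_last(x: Tensor) -> Tensor:
    """Softmax over the last axis, stabilized by a detached max subtraction."""
    shift = Tensor(x.data.max(axis=-1, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=-1, keepdims=True)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + eps) ** -0.5 * gain + bias


def gelu(x: Tensor) -> Tensor:
    # tanh approximation
    c = np.sqrt(2.0 / np.pi)
    return 0.5 * x * (1.0 + (c * (x + 0.044715 * x ** 3.0)).tanh())


def l2_normalize(x: Tensor, eps: float = 1e-12) -> Tensor:
    """Row-normalize the last axis to unit Euclidean norm."""
    sq = (x * x).sum(axis=-1, keepdims=True)
    return x * (sq + eps) ** -0.5


class Adam:
    """Adam optimizer over a dict of named Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
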