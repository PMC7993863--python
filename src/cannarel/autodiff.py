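"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to express and train the relation-extraction network
— elementwise arithmetic with broadcasting, matmul, the activations,
softmax, reductions, concatenation/slicing, embedding lookup and a
same-length 1-D convolution — plus Adam and Adadelta optimizers.  Arrays
are float64 throughout so gradient checks against brute-force oracles hold
tightly.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "Adam", "Adadelta", "SGD"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph -------------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad only valid for scalars")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:
                node.grad = g if node.grad is None else node.grad + g
                continue
            outs = node._backward(g)
            for p, pg in zip(node._parents, outs):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- elementwise arithmetic --------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data
        return Tensor(
            out_data,
            _parents=(self, other),
            _backward=lambda g: (
                _unbroadcast(g, self.shape),
                _unbroadcast(g, other.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor(-self.data, _parents=(self,), _backward=lambda g: (-g,))

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        return Tensor(
            self.data * other.data,
            _parents=(self, other),
            _backward=lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        out = self.data**p
        return Tensor(
            out,
            _parents=(self,),
            _backward=lambda g: (g * p * self.data ** (p - 1),),
        )

    # -- linear algebra ----------------------------------------------------

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)

        def bwd(g: np.ndarray):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:  # inner product
                return g * b, g * a
            if a.ndim == 1:  # (k,) @ (k,n) -> (n,)
                return g @ b.T, np.outer(a, g)
            if b.ndim == 1:  # (m,k) @ (k,) -> (m,)
                return np.outer(g, b), a.T @ g
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor(self.data @ other.data, _parents=(self, other), _backward=bwd)

    def transpose(self, *axes: int) -> "Tensor":
        ax = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(ax)
        return Tensor(
            self.data.transpose(ax),
            _parents=(self,),
            _backward=lambda g: (g.transpose(inv),),
        )

    def reshape(self, *shape: int) -> "Tensor":
        old = self.shape
        return Tensor(
            self.data.reshape(shape),
            _parents=(self,),
            _backward=lambda g: (g.reshape(old),),
        )

    def __getitem__(self, idx) -> "Tensor":
        def bwd(g: np.ndarray):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor(self.data[idx], _parents=(self,), _backward=bwd)

    def take_rows(self, indices: np.ndarray) -> "Tensor":
        """Embedding lookup: rows gathered by integer index, scatter-add backward."""
        indices = np.asarray(indices, dtype=np.int64)

        def bwd(g: np.ndarray):
            out = np.zeros_like(self.data)
            np.add.at(out, indices, g)
            return (out,)

        return Tensor(self.data[indices], _parents=(self,), _backward=bwd)

    # -- activations -------------------------------------------------------

    def tanh(self) -> "Tensor":
        out = np.tanh(self.data)
        return Tensor(out, _parents=(self,), _backward=lambda g: (g * (1 - out**2),))

    def sigmoid(self) -> "Tensor":
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return Tensor(out, _parents=(self,), _backward=lambda g: (g * out * (1 - out),))

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor(self.data * mask, _parents=(self,), _backward=lambda g: (g * mask,))

    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        return Tensor(out, _parents=(self,), _backward=lambda g: (g * out,))

    def log(self) -> "Tensor":
        return Tensor(
            np.log(self.data), _parents=(self,), _backward=lambda g: (g / self.data,)
        )

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bwd(g: np.ndarray):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,), _backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=axis, keepdims=True)

        def bwd(g: np.ndarray):
            dot = (g * out).sum(axis=axis, keepdims=True)
            return (out * (g - dot),)

        return Tensor(out, _parents=(self,), _backward=bwd)

    def conv1d_same(self, weight: "Tensor", bias: "Tensor", window: int) -> "Tensor":
        """Same-length 1-D convolution over a (n, d_in) sequence.

        ``weight`` has shape (window*d_in, d_out).  The sequence is
        zero-padded by floor/ceil((window-1)/2) on the left/right so every
        window size yields exactly n outputs (valid even for n < window).
        """
        x = self.data
        n, d_in = x.shape
        lpad = (window - 1) // 2
        rpad = window - 1 - lpad
        xp = np.zeros((n + lpad + rpad, d_in))
        xp[lpad : lpad + n] = x
        windows = np.lib.stride_tricks.sliding_window_view(xp, (window, d_in))
        cols = windows.reshape(n, window * d_in)  # (n, window*d_in)
        out = cols @ weight.data + bias.data

        def bwd(g: np.ndarray):
            gw = cols.T @ g
            gb = g.sum(axis=0)
            gcols = g @ weight.data.T  # (n, window*d_in)
            gxp = np.zeros_like(xp)
            gwin = gcols.reshape(n, window, d_in)
            for j in range(window):
                gxp[j : j + n] += gwin[:, j, :]
            return gxp[lpad : lpad + n], gw, gb

        return Tensor(out, _parents=(self, weight, bias), _backward=bwd)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g: np.ndarray):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=bwd,
    )


# -- optimizers ------------------------------------------------------------


class _Optimizer:
    def __init__(self, params: Iterable[Tensor]):
        self.params = [p for p in params if p.requires_grad]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:  # pragma: no cover - interface
        raise NotImplementedError


class SGD(_Optimizer):
    def __init__(self, params, lr: float = 0.1):
        super().__init__(params)
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad


class Adam(_Optimizer):
    def __init__(self, params, lr: float = 0.001, betas=(0.9, 0.999), eps: float = 1e-8):
        super().__init__(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad**2 - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adadelta(_Optimizer):
    def __init__(self, params, rho: float = 0.95, eps: float = 1e-6, lr: float = 1.0):
        super().__init__(params)
        self.rho, self.eps, self.lr = rho, eps, lr
        self.sq_grad = [np.zeros_like(p.data) for p in self.params]
        self.sq_delta = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, sg, sd in zip(self.params, self.sq_grad, self.sq_delta):
            if p.grad is None:
                continue
            sg *= self.rho
            sg += (1 - self.rho) * p.grad**2
            delta = np.sqrt(sd + self.eps) / np.sqrt(sg + self.eps) * p.grad
            sd *= self.rho
            sd += (1 - self.rho) * delta**2
            p.data -= self.lr * delta
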