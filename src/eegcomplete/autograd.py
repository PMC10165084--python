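"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for a small attention encoder-decoder: broadcasting
arithmetic, batched matmul, reshapes/transposes, slicing, gather/scatter on
unique row indices, reductions, elementwise nonlinearities, and an Adam
optimizer.  Gradients are accumulated by topological-order backpropagation.

Everything is float64.  The engine favours clarity over speed; the networks
trained with it are small (tens of thousands of parameters).
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        return out

    def _acc(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other))

        def backward() -> None:
            self._acc(_unbroadcast(out.grad, self.data.shape))
            other._acc(_unbroadcast(out.grad, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = self._make(-self.data, (self,))

        def backward() -> None:
            self._acc(-out.grad)

        out._backward = backward
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other))

        def backward() -> None:
            self._acc(_unbroadcast(out.grad * other.data, self.data.shape))
            other._acc(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        out = self._make(self.data / other.data, (self, other))

        def backward() -> None:
            self._acc(_unbroadcast(out.grad / other.data, self.data.shape))
            other._acc(
                _unbroadcast(-out.grad * self.data / other.data**2, other.data.shape)
            )

        out._backward = backward
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) / self

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = self._make(self.data @ other.data, (self, other))

        def backward() -> None:
            a, b, g = self.data, other.data, out.grad
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._acc(_unbroadcast(ga, a.shape))
            other._acc(_unbroadcast(gb, b.shape))

        out._backward = backward
        return out

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self._make(self.data.reshape(shape), (self,))

        def backward() -> None:
            self._acc(out.grad.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = self._make(self.data.transpose(axes), (self,))
        inverse = np.argsort(axes)

        def backward() -> None:
            self._acc(out.grad.transpose(inverse))

        out._backward = backward
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = self._make(np.swapaxes(self.data, a, b), (self,))

        def backward() -> None:
            self._acc(np.swapaxes(out.grad, a, b))

        out._backward = backward
        return out

    def __getitem__(self, key) -> "Tensor":
        """Basic slicing only (gradient scattered back into zeros)."""
        out = self._make(self.data[key], (self,))

        def backward() -> None:
            g = np.zeros_like(self.data)
            g[key] = out.grad
            self._acc(g)

        out._backward = backward
        return out

    def pad_axis(self, axis: int, before: int, after: int, value: float = 0.0) -> "Tensor":
        """Constant-pad one axis."""
        pads = [(0, 0)] * self.data.ndim
        pads[axis] = (before, after)
        out = self._make(np.pad(self.data, pads, constant_values=value), (self,))
        sl = [slice(None)] * self.data.ndim
        sl[axis] = slice(before, before + self.data.shape[axis])
        sl = tuple(sl)

        def backward() -> None:
            self._acc(out.grad[sl])

        out._backward = backward
        return out

    # -- gather / scatter on rows of axis -2 ----------------------------------
    def take_rows(self, index: np.ndarray) -> "Tensor":
        """Gather rows along axis -2; ``index`` broadcasts over leading axes.

        ``index`` has shape ``self.shape[:-2] + (k,)``; entries must be unique
        per leading slot for the scatter in backward to be exact.
        """
        idx = index[..., None]
        out = self._make(np.take_along_axis(self.data, idx, axis=-2), (self,))

        def backward() -> None:
            g = np.zeros_like(self.data)
            np.put_along_axis(g, idx, out.grad, axis=-2)
            self._acc(g)

        out._backward = backward
        return out

    def set_rows(self, index: np.ndarray, rows: "Tensor") -> "Tensor":
        """Return a copy with rows at ``index`` (axis -2) replaced by ``rows``.

        Indices must be unique per leading slot.
        """
        rows = self._lift(rows)
        idx = index[..., None]
        data = self.data.copy()
        np.put_along_axis(data, idx, rows.data, axis=-2)
        out = self._make(data, (self, rows))

        def backward() -> None:
            g_base = out.grad.copy()
            g_rows = np.take_along_axis(out.grad, idx, axis=-2)
            np.put_along_axis(g_base, idx, 0.0, axis=-2)
            self._acc(g_base)
            rows._acc(g_rows)

        out._backward = backward
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward() -> None:
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._acc(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = math.prod(self.data.shape[a] for a in axes)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max along one axis; gradient flows to the (first) argmax."""
        data = self.data.max(axis=axis, keepdims=keepdims)
        out = self._make(data, (self,))
        argmax = np.expand_dims(self.data.argmax(axis=axis), axis)

        def backward() -> None:
            g = out.grad if keepdims else np.expand_dims(out.grad, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, argmax, g, axis=axis)
            self._acc(full)

        out._backward = backward
        return out

    # -- elementwise ----------------------------------------------------------
    def exp(self) -> "Tensor":
        out = self._make(np.exp(self.data), (self,))

        def backward() -> None:
            self._acc(out.grad * out.data)

        out._backward = backward
        return out

    def log(self) -> "Tensor":
        out = self._make(np.log(self.data), (self,))

        def backward() -> None:
            self._acc(out.grad / self.data)

        out._backward = backward
        return out

    def sqrt(self) -> "Tensor":
        out = self._make(np.sqrt(self.data), (self,))

        def backward() -> None:
            self._acc(out.grad * 0.5 / out.data)

        out._backward = backward
        return out

    def tanh(self) -> "Tensor":
        out = self._make(np.tanh(self.data), (self,))

        def backward() -> None:
            self._acc(out.grad * (1.0 - out.data**2))

        out._backward = backward
        return out

    def elu(self, alpha: float = 1.0) -> "Tensor":
        pos = self.data > 0
        data = np.where(pos, self.data, alpha * np.expm1(self.data))
        out = self._make(data, (self,))

        def backward() -> None:
            self._acc(out.grad * np.where(pos, 1.0, data + alpha))

        out._backward = backward
        return out

    def relu(self) -> "Tensor":
        pos = self.data > 0
        out = self._make(np.where(pos, self.data, 0.0), (self,))

        def backward() -> None:
            self._acc(out.grad * pos)

        out._backward = backward
        return out

    # -- composites -----------------------------------------------------------
    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def dropout(self, p: float, rng: np.random.Generator | None) -> "Tensor":
        """Inverted dropout; identity when ``rng`` is None (inference)."""
        if rng is None or p <= 0.0:
            return self
        mask = (rng.random(self.data.shape) >= p) / (1.0 - p)
        return self * Tensor(mask)

    # -- backprop -------------------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from a scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.requires_grad and node.grad is not None:
                node._backward()


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
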