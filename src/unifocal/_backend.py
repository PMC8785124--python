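"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

Every loss in this package is written against the small dispatch layer at the
bottom of this module (:func:`log`, :func:`clip`, :func:`asum`, ...), so the same
code path produces either a plain float (numpy input) or a differentiable scalar
(:class:`Tensor` input).  Gradients with respect to the class-probability map are
obtained with :func:`value_and_grad`; the tiny benchmark segmenter trains through
the same machinery (see :func:`conv2d`).

The op set is deliberately small: elementwise arithmetic, scalar powers,
log/exp, reductions, reshape, slicing, matmul, relu, clip and a same-padding 2-D
convolution.  Broadcasting follows numpy semantics; gradients of broadcast
operands are summed back onto the operand shape.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "value_and_grad",
    "conv2d",
    "softmax",
    "relu",
    "log",
    "clip",
    "power",
    "asum",
    "reshape",
    "mean_per_item",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting expanded."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    # Keep numpy from absorbing us into its own ufunc machinery: binary ops with
    # an ndarray on the left must fall through to our reflected operators.
    __array_ufunc__ = None
    __array_priority__ = 1000

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, _parents: tuple = (), _backward=None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data  # dtype preserved: float32 models train at float32
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Reverse-mode sweep seeding d(self)/d(self) = 1."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs from training loops can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward():
            self._accumulate(_unbroadcast(out.grad, self.shape))
            other._accumulate(_unbroadcast(out.grad, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward():
            self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
            other._accumulate(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return (-self) + other

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * (other ** -1.0)

    def __rtruediv__(self, other):
        return (self ** -1.0) * other

    def __pow__(self, exponent: float):
        exponent = float(exponent)
        out = Tensor(self.data ** exponent, (self,))

        def backward():
            self._accumulate(out.grad * exponent * self.data ** (exponent - 1.0))

        out._backward = backward
        return out

    # -- transcendental ---------------------------------------------------
    def log(self):
        out = Tensor(np.log(self.data), (self,))

        def backward():
            self._accumulate(out.grad / self.data)

        out._backward = backward
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), (self,))

        def backward():
            self._accumulate(out.grad * out.data)

        out._backward = backward
        return out

    # -- reductions / shape -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward():
            grad = out.grad
            if axis is not None and not keepdims:
                axes = (axis,) if np.isscalar(axis) else tuple(axis)
                for ax in sorted(a % self.ndim for a in axes):
                    grad = np.expand_dims(grad, ax)
            self._accumulate(np.broadcast_to(grad, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[a % self.ndim] for a in ((axis,) if np.isscalar(axis) else axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    def reshape(self, shape):
        out = Tensor(self.data.reshape(shape), (self,))

        def backward():
            self._accumulate(out.grad.reshape(self.shape))

        out._backward = backward
        return out

    def __getitem__(self, index):
        out = Tensor(self.data[index], (self,))

        def backward():
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            np.add.at(self.grad, index, out.grad)

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data, (self, other))

        def backward():
            self._accumulate(out.grad @ other.data.T)
            other._accumulate(self.data.T @ out.grad)

        out._backward = backward
        return out

    # -- clamping ----------------------------------------------------------
    def clip(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), (self,))
        inside = (self.data > lo) & (self.data < hi)

        def backward():
            self._accumulate(out.grad * inside)

        out._backward = backward
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))

        def backward():
            self._accumulate(out.grad * (self.data > 0.0))

        out._backward = backward
        return out

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape})"


# ---------------------------------------------------------------------------
# Composite ops used by the tiny segmentation model.
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    return x.relu()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; the max shift is treated as a constant."""
    shift = np.max(x.data, axis=axis, keepdims=True)
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-item, per-channel normalisation over spatial axes of (B, H, W, C).

    No learnable affine parameters; keeps feature scales bounded so the final
    softmax cannot saturate irrecoverably early in training.
    """
    axes = tuple(range(1, x.ndim - 1))
    mu = x.mean(axis=axes, keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=axes, keepdims=True)
    return centred * ((var + eps) ** -0.5)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding 2-D convolution over (batch, H, W, C_in) maps.

    Implemented as im2col + matmul so both passes hit BLAS.  ``w`` has shape
    (kh, kw, C_in, C_out); ``b`` has shape (C_out,).
    """
    batch, height, width, c_in = x.shape
    kh, kw, _, c_out = w.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    # (B, H, W, C_in, kh, kw) -> (B*H*W, kh*kw*C_in), matching w.reshape order
    cols = sliding_window_view(xp, (kh, kw), axis=(1, 2))
    cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))
    cols2 = cols.reshape(batch * height * width, kh * kw * c_in)
    w2 = w.data.reshape(kh * kw * c_in, c_out)
    out_data = (cols2 @ w2 + b.data).reshape(batch, height, width, c_out)
    out = Tensor(out_data, (x, w, b))

    def backward():
        g = out.grad.reshape(batch * height * width, c_out)
        w._accumulate((cols2.T @ g).reshape(w.shape))
        b._accumulate(g.sum(axis=0))
        dcols = (g @ w2.T).reshape(batch, height, width, kh, kw, c_in)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i:i + height, j:j + width, :] += dcols[:, :, :, i, j, :]
        x._accumulate(dxp[:, ph:ph + height, pw:pw + width, :])

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# Dispatch layer: the losses call these and never touch numpy/Tensor directly.
# ---------------------------------------------------------------------------

def log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def clip(x, lo: float, hi: float):
    return x.clip(lo, hi) if isinstance(x, Tensor) else np.clip(x, lo, hi)


def power(x, exponent: float):
    return x ** exponent


def asum(x, axis=None, keepdims: bool = False):
    if isinstance(x, Tensor):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.sum(x, axis=axis, keepdims=keepdims)


def reshape(x, shape):
    return x.reshape(shape)


def mean_per_item(x):
    """Mean over all non-batch axes: (B, ...) -> (B,)."""
    batch = x.shape[0]
    n = int(np.prod(x.shape[1:])) if x.ndim > 1 else 1
    flat = reshape(x, (batch, n))
    return asum(flat, axis=1) * (1.0 / n)


def value_and_grad(loss_fn, p: np.ndarray, *args, **kwargs):
    """Evaluate ``loss_fn`` at probability map ``p`` and differentiate w.r.t. it.

    ``loss_fn`` must be one of this package's loss functions (or any callable
    written against the dispatch layer) and is called as
    ``loss_fn(Tensor(p), *args, **kwargs)``; it returns a scalar Tensor on that
    path.  Returns ``(value, grad)`` with ``grad`` shaped like ``p``.
    """
    t = Tensor(np.asarray(p, dtype=np.float64))
    out = loss_fn(t, *args, **kwargs)
    out.backward()
    grad = t.grad if t.grad is not None else np.zeros_like(t.data)
    return out.item(), grad
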