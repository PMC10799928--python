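"""Minimal reverse-mode automatic differentiation on numpy arrays.

The reconstruction networks in this package are small 1D models (windowed
attention, convolutions, MLPs) operating on 128-sample windows, so a compact
tape-based engine over numpy is sufficient to train them on a CPU.  The op set
is exactly what the architectures need: broadcasting arithmetic, batched
matmul, dilated 1D convolution, softmax, GELU/ReLU, reductions, reshapes,
cyclic roll and table gather (for relative position biases).

Gradients of every primitive are checked against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents: tuple = ()
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g * 0.5 / np.sqrt(self.data))

        return Tensor._make(out_data, (self,), backward)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        in_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accumulate(g.reshape(in_shape))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = np.transpose(self.data, axes)

        def backward(g):
            self._accumulate(np.transpose(g, inv))

        return Tensor._make(out_data, (self,), backward)

    def roll(self, shift: int, axis: int):
        out_data = np.roll(self.data, shift, axis=axis)

        def backward(g):
            self._accumulate(np.roll(g, -shift, axis=axis))

        return Tensor._make(out_data, (self,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        in_shape = self.data.shape

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, in_shape).copy())
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, in_shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ activations
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(out_data, (self,), backward)

    def gelu(self):
        # tanh approximation of GELU; smooth, closed-form derivative
        c = np.sqrt(2.0 / np.pi)
        x = self.data
        u = c * (x + 0.044715 * x**3)
        t = np.tanh(u)
        out_data = 0.5 * x * (1.0 + t)

        def backward(g):
            du = c * (1.0 + 3 * 0.044715 * x**2)
            d = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * du
            self._accumulate(g * d)

        return Tensor._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            self._accumulate(s * (g - (g * s).sum(axis=axis, keepdims=True)))

        return Tensor._make(s, (self,), backward)

    # ---------------------------------------------------------- linear algebra
    def matmul(self, other: "Tensor"):
        other = Tensor._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # ------------------------------------------------------------ convolution
    def conv1d(self, weight: "Tensor", bias: "Tensor" = None, *,
               padding: str = "same", dilation: int = 1):
        """Dilated 1D convolution over (batch, time, c_in) with kernel
        (k, c_in, c_out).  padding: 'same' (zero-padded, length preserving,
        odd k) or 'causal' (left-padded)."""
        x = self.data
        w = weight.data
        k, c_in, c_out = w.shape
        if x.shape[-1] != c_in:
            raise ValueError(f"channel mismatch: input {x.shape[-1]}, kernel {c_in}")
        span = dilation * (k - 1)
        if padding == "same":
            if k % 2 == 0:
                raise ValueError("'same' padding requires odd kernel length")
            left = right = span // 2
        elif padding == "causal":
            left, right = span, 0
        else:
            raise ValueError(f"unknown padding {padding!r}")
        b_, t = x.shape[0], x.shape[1]
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        out = np.zeros((b_, t, c_out))
        for j in range(k):
            out += xp[:, j * dilation : j * dilation + t, :] @ w[j]
        if bias is not None:
            out += bias.data

        def backward(g):
            if self.requires_grad:
                gxp = np.zeros_like(xp)
                for j in range(k):
                    gxp[:, j * dilation : j * dilation + t, :] += g @ w[j].T
                self._accumulate(gxp[:, left : left + t, :])
            if weight.requires_grad:
                gw = np.empty_like(w)
                for j in range(k):
                    seg = xp[:, j * dilation : j * dilation + t, :]
                    gw[j] = np.einsum("bti,bto->io", seg, g)
                weight._accumulate(gw)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 1)))

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out, parents, backward)

    # ----------------------------------------------------------------- gather
    def gather(self, idx: np.ndarray):
        """Index the leading axis of a parameter table: out = table[idx]."""
        idx = np.asarray(idx)
        out_data = self.data[idx]

        def backward(g):
            gt = np.zeros_like(self.data)
            np.add.at(gt, idx, g)
            self._accumulate(gt)

        return Tensor._make(out_data, (self,), backward)

    def slice_first(self, i: int):
        """Index the leading axis, dropping it: out = x[i]."""
        out_data = self.data[i]

        def backward(g):
            gx = np.zeros_like(self.data)
            gx[i] = g
            self._accumulate(gx)

        return Tensor._make(out_data, (self,), backward)

    def slice_time(self, start: int, stop: int):
        """Slice axis 1 (time) of a (batch, time, ...) tensor."""
        out_data = self.data[:, start:stop]

        def backward(g):
            gx = np.zeros_like(self.data)
            gx[:, start:stop] = g
            self._accumulate(gx)

        return Tensor._make(out_data, (self,), backward)
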