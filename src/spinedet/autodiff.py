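"""A minimal reverse-mode automatic differentiation core on numpy arrays.

Just enough machinery to express and train the toy landmark network:
tensors wrap ndarrays, operations build a graph of closures, and
``backward()`` runs the chain rule in reverse topological order.  Ops
cover elementwise arithmetic with broadcasting, matmul, the activations
and reductions the losses need, and the two structured ops (3x3
convolution via im2col, nearest-neighbour 2x upsampling) the
encoder-decoder is made of.  Gradients are checked against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "minimum", "conv2d", "upsample2x"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus the backward closure that built it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() needs a scalar output")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
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
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out_data, (self,), backward)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        x = self.data
        out_data = np.where(
            x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))), np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))
        )

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def abs(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), backward)

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient passes only inside [lo, hi]."""
        out_data = np.clip(self.data, lo, hi)
        inside = (self.data > lo) & (self.data < hi)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * inside)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions and reshaping -----------------------------------------
    def sum(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(np.full_like(self.data, float(g)))

        return Tensor._make(self.data.sum(), (self,), backward)

    def mean(self):
        n = self.data.size

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.full_like(self.data, float(g) / n))

        return Tensor._make(self.data.mean(), (self,), backward)

    def mean_axes(self, axes: tuple):
        """Mean over the given axes (kept for global average pooling)."""
        out_data = self.data.mean(axis=axes)
        count = np.prod([self.data.shape[a] for a in axes])

        def backward(g):
            if self.requires_grad:
                g_full = np.expand_dims(g, axes)
                self._accumulate(
                    np.broadcast_to(g_full, self.data.shape) / count
                )

        return Tensor._make(out_data, (self,), backward)

    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(
                    _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape)
                )
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)


def minimum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise minimum; gradient follows the selected branch."""
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    take_a = a.data <= b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * take_a, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * ~take_a, b.data.shape))

    return Tensor._make(np.where(take_a, a.data, b.data), (a, b), backward)


def concat(tensors: list, axis: int = 1) -> Tensor:
    """Concatenate along ``axis``."""
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._make(out_data, tuple(tensors), backward)


def _im2col(x: np.ndarray, stride: int) -> np.ndarray:
    """(B, C, H, W), 1-padded 3x3 patches -> (B, C*9, H_out*W_out)."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    h_out = (h + 2 - 3) // stride + 1
    w_out = (w + 2 - 3) // stride + 1
    cols = np.empty((b, c, 9, h_out, w_out), dtype=x.dtype)
    for i in range(3):
        for j in range(3):
            cols[:, :, i * 3 + j] = xp[
                :, :, i : i + stride * h_out : stride, j : j + stride * w_out : stride
            ]
    return cols.reshape(b, c * 9, h_out * w_out)


def _col2im(cols: np.ndarray, x_shape: tuple, stride: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    b, c, h, w = x_shape
    h_out = (h + 2 - 3) // stride + 1
    w_out = (w + 2 - 3) // stride + 1
    cols = cols.reshape(b, c, 9, h_out, w_out)
    xp = np.zeros((b, c, h + 2, w + 2), dtype=cols.dtype)
    for i in range(3):
        for j in range(3):
            np.add.at(
                xp,
                (
                    slice(None),
                    slice(None),
                    slice(i, i + stride * h_out, stride),
                    slice(j, j + stride * w_out, stride),
                ),
                cols[:, :, i * 3 + j],
            )
    return xp[:, :, 1:-1, 1:-1]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1) -> Tensor:
    """3x3 convolution, padding 1, via im2col.

    ``x``: (B, C_in, H, W); ``weight``: (C_out, C_in, 3, 3); ``bias``:
    (C_out,).  Returns (B, C_out, H/stride, W/stride).
    """
    b, c_in, h, w = x.data.shape
    c_out = weight.data.shape[0]
    cols = _im2col(x.data, stride)                        # (B, C*9, P)
    w_mat = weight.data.reshape(c_out, c_in * 9)
    out = w_mat @ cols + bias.data[None, :, None]          # (B, C_out, P)
    h_out = (h + 2 - 3) // stride + 1
    w_out = (w + 2 - 3) // stride + 1
    out = out.reshape(b, c_out, h_out, w_out)

    def backward(g):
        g_mat = g.reshape(b, c_out, -1)                    # (B, C_out, P)
        if weight.requires_grad:
            gw = np.einsum("bop,bcp->oc", g_mat, cols).reshape(weight.data.shape)
            weight._accumulate(gw)
        if bias.requires_grad:
            bias._accumulate(g_mat.sum(axis=(0, 2)))
        if x.requires_grad:
            g_cols = np.einsum("oc,bop->bcp", w_mat, g_mat)
            x._accumulate(_col2im(g_cols, x.data.shape, stride))

    return Tensor._make(out, (x, weight, bias), backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of (B, C, H, W)."""
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if x.requires_grad:
            b, c, h2, w2 = g.shape
            x._accumulate(
                g.reshape(b, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            )

    return Tensor._make(out_data, (x,), backward)
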