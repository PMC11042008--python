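"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ``numpy.ndarray`` and records the operations
applied to it; :meth:`Tensor.backward` walks the recorded graph in reverse
topological order and accumulates gradients into every tensor created with
``requires_grad=True``. The op set is exactly what the segmentation models in
this package need: broadcast arithmetic, (batched) matmul, reductions,
pointwise nonlinearities, shape ops, 2-D convolution/pooling, bilinear
resizing and the space-to-depth rearrangement.

All arithmetic is float32; gradients are float32 arrays of the same shape as
the data they belong to.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "maxpool2d",
    "resize_bilinear",
    "softmax",
    "space_to_depth",
    "space_to_depth_inverse",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    """Overflow-safe logistic function."""
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs here can be a few hundred nodes deep
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
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- introspection -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        p = float(exponent)
        out_data = a.data ** np.float32(p)

        def backward(g):
            a._accum(g * (p * a.data ** np.float32(p - 1.0)))

        return Tensor._make(out_data, (a,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g @ b.data.swapaxes(-1, -2), a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(a.data.swapaxes(-1, -2) @ g, b.data.shape))

        return Tensor._make(a.data @ b.data, (a, b), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims, dtype=np.float32)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).astype(np.float32))

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise ---------------------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = _sigmoid(a.data)

        def backward(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def silu(self):
        a = self
        sig = _sigmoid(a.data)
        out_data = a.data * sig

        def backward(g):
            a._accum(g * (sig * (1.0 + a.data * (1.0 - sig))))

        return Tensor._make(out_data, (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            a._accum(g * (0.5 / out_data))

        return Tensor._make(out_data, (a,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through unclamped entries."""
        a = self
        mask = (a.data > lo) & (a.data < hi)

        def backward(g):
            a._accum(g * mask)

        return Tensor._make(np.clip(a.data, lo, hi), (a,), backward)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        in_shape = a.data.shape

        def backward(g):
            a._accum(g.reshape(in_shape))

        return Tensor._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def backward(g):
            a._accum(g.transpose(inv))

        return Tensor._make(np.ascontiguousarray(a.data.transpose(axes)), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            dx = np.zeros_like(a.data)
            np.add.at(dx, idx, g)
            a._accum(dx)

        return Tensor._make(a.data[idx].copy(), (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


# -- convolution ----------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int, dilation: int):
    b, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = x.shape[2], x.shape[3]
    h_out = (hp - dilation * (kh - 1) - 1) // stride + 1
    w_out = (wp - dilation * (kw - 1) - 1) // stride + 1
    cols = np.empty((b, c, kh, kw, h_out, w_out), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            ii, jj = i * dilation, j * dilation
            cols[:, :, i, j] = x[:, :, ii : ii + stride * h_out : stride, jj : jj + stride * w_out : stride]
    return cols, (hp, wp, h_out, w_out)


def _col2im(dcols: np.ndarray, x_shape, stride: int, padding: int, dilation: int):
    b, c, h, w = x_shape
    kh, kw = dcols.shape[2], dcols.shape[3]
    h_out, w_out = dcols.shape[4], dcols.shape[5]
    hp, wp = h + 2 * padding, w + 2 * padding
    dx = np.zeros((b, c, hp, wp), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            ii, jj = i * dilation, j * dilation
            dx[:, :, ii : ii + stride * h_out : stride, jj : jj + stride * w_out : stride] += dcols[:, :, i, j]
    if padding:
        dx = dx[:, :, padding:-padding, padding:-padding]
    return dx


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (C_out, C_in, kH, kW)."""
    c_out, c_in, kh, kw = weight.data.shape
    if x.data.shape[1] != c_in:
        raise ValueError(f"conv2d: input has {x.data.shape[1]} channels, weight expects {c_in}")
    cols, (_, _, h_out, w_out) = _im2col(x.data, kh, kw, stride, padding, dilation)
    b = x.data.shape[0]
    k = c_in * kh * kw
    cols2 = cols.reshape(b, k, h_out * w_out)
    w2 = weight.data.reshape(c_out, k)
    out = np.matmul(w2, cols2).reshape(b, c_out, h_out, w_out)
    if bias is not None:
        out = out + bias.data.reshape(1, c_out, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g2 = g.reshape(b, c_out, h_out * w_out)
        if weight.requires_grad:
            dw = np.einsum("bof,bkf->ok", g2, cols2, optimize=True)
            weight._accum(dw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)).reshape(bias.data.shape))
        if x.requires_grad:
            dcols2 = np.matmul(w2.T, g2)
            dcols = dcols2.reshape(b, c_in, kh, kw, h_out, w_out)
            x._accum(_col2im(dcols, x.data.shape, stride, padding, dilation))

    return Tensor._make(out, parents, backward)


def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    b, c, h, w = x.data.shape
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)), constant_values=-np.inf)
    cols, (_, _, h_out, w_out) = _im2col(xp, kernel, kernel, stride, 0, 1)
    cols = cols.reshape(b, c, kernel * kernel, h_out, w_out)
    idx = cols.argmax(axis=2)
    out = np.take_along_axis(cols, idx[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        dcols = np.zeros_like(cols)
        np.put_along_axis(dcols, idx[:, :, None], g[:, :, None], axis=2)
        dcols = dcols.reshape(b, c, kernel, kernel, h_out, w_out)
        hp, wp = h + 2 * padding, w + 2 * padding
        dxp = np.zeros((b, c, hp, wp), dtype=g.dtype)
        for i in range(kernel):
            for j in range(kernel):
                dxp[:, :, i : i + stride * h_out : stride, j : j + stride * w_out : stride] += dcols[:, :, i, j]
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accum(dxp)

    return Tensor._make(out, (x,), backward)


def _bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic interpolation matrix (n_out, n_in), half-pixel centers."""
    a = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        i0 = int(np.floor(src))
        frac = src - i0
        i0c = min(max(i0, 0), n_in - 1)
        i1c = min(max(i0 + 1, 0), n_in - 1)
        a[o, i0c] += 1.0 - frac
        a[o, i1c] += frac
    return a


def resize_bilinear(x: Tensor, scale: int) -> Tensor:
    """Upsample H and W by an integer factor with bilinear interpolation."""
    b, c, h, w = x.data.shape
    ah = _bilinear_matrix(h, h * scale)
    aw = _bilinear_matrix(w, w * scale)
    out = np.einsum("oh,bchw,pw->bcop", ah, x.data, aw, optimize=True)

    def backward(g):
        x._accum(np.einsum("oh,bcop,pw->bchw", ah, g, aw, optimize=True))

    return Tensor._make(out, (x,), backward)


# -- space-to-depth (Focus slicing) ---------------------------------------

# Parity order of the four sub-grids: (even row, even col), (odd, even),
# (even, odd), (odd, odd). Any fixed order works; this one is the package canon.
SLICE_ORDER = ((0, 0), (1, 0), (0, 1), (1, 1))


def space_to_depth(x: Tensor) -> Tensor:
    """Rearrange each 2x2 pixel block into 4 channels (lossless, invertible)."""
    b, c, h, w = x.data.shape
    if h % 2:
        raise ValueError(f"space_to_depth: height {h} is odd")
    if w % 2:
        raise ValueError(f"space_to_depth: width {w} is odd")
    parts = [x.data[:, :, r::2, cc::2] for r, cc in SLICE_ORDER]
    out = np.concatenate(parts, axis=1)

    def backward(g):
        dx = np.empty_like(x.data)
        for k, (r, cc) in enumerate(SLICE_ORDER):
            dx[:, :, r::2, cc::2] = g[:, k * c : (k + 1) * c]
        x._accum(dx)

    return Tensor._make(out, (x,), backward)


def space_to_depth_inverse(y: np.ndarray) -> np.ndarray:
    """Exact inverse of the slicing rearrangement (numpy arrays)."""
    b, c4, h2, w2 = y.shape
    if c4 % 4:
        raise ValueError("channel count not divisible by 4")
    c = c4 // 4
    x = np.empty((b, c, h2 * 2, w2 * 2), dtype=y.dtype)
    for k, (r, cc) in enumerate(SLICE_ORDER):
        x[:, :, r::2, cc::2] = y[:, k * c : (k + 1) * c]
    return x
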