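"""Minimal reverse-mode autodiff on numpy arrays.

Implements exactly the operator set the segmentation network needs:
elementwise arithmetic, reductions, matmul, ReLU, softmax, 2D convolution
(im2col), max-pooling, pixel shuffle, channel concatenation and batch
normalization (the latter lives in :mod:`csfseg.nn.layers`). Everything is
deterministic: same inputs and seeds give bit-identical results.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad", "concat", "matmul"]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to the operand's shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- plumbing -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.result_type(self.data, np.float32))
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data, dtype=np.result_type(self.data, np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _track(out: "Tensor", prev: Sequence["Tensor"], backward) -> "Tensor":
        if _grad_enabled and any(p.requires_grad or p._prev for p in prev):
            out.requires_grad = any(p.requires_grad for p in prev)
            out._prev = tuple(prev)
            out._backward = backward
        return out

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    # -- elementwise --------------------------------------------------------
    def __add__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data + other.data)

        def backward(g):
            if self.requires_grad or self._prev:
                self._accumulate(_sum_to_shape(g, self.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_sum_to_shape(g, other.shape))

        return Tensor._track(out, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data)

        def backward(g):
            self._accumulate(-g)

        return Tensor._track(out, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data * other.data)

        def backward(g):
            if self.requires_grad or self._prev:
                self._accumulate(_sum_to_shape(g * other.data, self.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_sum_to_shape(g * self.data, other.shape))

        return Tensor._track(out, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data / other.data)

        def backward(g):
            if self.requires_grad or self._prev:
                self._accumulate(_sum_to_shape(g / other.data, self.shape))
            if other.requires_grad or other._prev:
                other._accumulate(
                    _sum_to_shape(-g * self.data / (other.data**2), other.shape)
                )

        return Tensor._track(out, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    # -- reductions / reshaping --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._track(out, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out = Tensor(self.data.reshape(shape))

        def backward(g):
            self._accumulate(g.reshape(orig))

        return Tensor._track(out, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes))

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor._track(out, (self,), backward)

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0))
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._track(out, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate((g - dot) * s)

        return Tensor._track(out, (self,), backward)

    # -- linear algebra -------------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = Tensor._wrap(other)
        out = Tensor(np.matmul(self.data, other.data))

        def backward(g):
            if self.requires_grad or self._prev:
                ga = np.matmul(g, other.data.swapaxes(-1, -2))
                self._accumulate(_sum_to_shape(ga, self.shape))
            if other.requires_grad or other._prev:
                gb = np.matmul(self.data.swapaxes(-1, -2), g)
                other._accumulate(_sum_to_shape(gb, other.shape))

        return Tensor._track(out, (self, other), backward)

    __matmul__ = matmul


def Parameter(data) -> Tensor:
    """A trainable tensor (float32)."""
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad or t._prev:
                t._accumulate(piece)

    return Tensor._track(out, tuple(tensors), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor._wrap(a).matmul(b)


# ---------------------------------------------------------------------------
# im2col machinery shared by convolution and pooling


def _out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def _im2col_view(xp: np.ndarray, kh: int, kw: int, stride: int):
    """Read-only (B, C, kh, kw, Hp, Wp) sliding-window view of a padded array."""
    B, C, H, W = xp.shape
    Hp = (H - kh) // stride + 1
    Wp = (W - kw) // stride + 1
    s = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        shape=(B, C, kh, kw, Hp, Wp),
        strides=(s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
        writeable=False,
    )


def _col2im(cols6: np.ndarray, xshape, kh, kw, stride, pad) -> np.ndarray:
    """Scatter-add a (B, C, kh, kw, Hp, Wp) gradient back onto the input grid."""
    B, C, H, W = xshape
    Hp, Wp = cols6.shape[4], cols6.shape[5]
    xp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=cols6.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * Hp : stride, j : j + stride * Wp : stride] += cols6[
                :, :, i, j
            ]
    if pad:
        return xp[:, :, pad : pad + H, pad : pad + W]
    return xp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2D convolution (cross-correlation), NCHW layout."""
    B, C, H, W = x.shape
    Cout, Cin, kh, kw = w.shape
    if Cin != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, kernel {Cin}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    view = _im2col_view(xp, kh, kw, stride)
    Hp, Wp = view.shape[4], view.shape[5]
    cols = np.ascontiguousarray(view).reshape(B, C * kh * kw, Hp * Wp)
    w2 = w.data.reshape(Cout, C * kh * kw)
    out_data = np.matmul(w2, cols).reshape(B, Cout, Hp, Wp)
    if b is not None:
        out_data = out_data + b.data.reshape(1, Cout, 1, 1)
    out = Tensor(out_data)

    def backward(g):
        g2 = g.reshape(B, Cout, Hp * Wp)
        if w.requires_grad or w._prev:
            gw = np.einsum("bol,bkl->ok", g2, cols, optimize=True)
            w._accumulate(gw.reshape(w.shape).astype(w.data.dtype, copy=False))
        if b is not None and (b.requires_grad or b._prev):
            b._accumulate(g2.sum(axis=(0, 2)).astype(b.data.dtype, copy=False))
        if x.requires_grad or x._prev:
            gcols = np.matmul(w2.T, g2)  # (B, C*kh*kw, L)
            gcols6 = gcols.reshape(B, C, kh, kw, Hp, Wp)
            x._accumulate(
                _col2im(gcols6, x.shape, kh, kw, stride, padding).astype(
                    x.data.dtype, copy=False
                )
            )

    return Tensor._track(out, (x, w) if b is None else (x, w, b), backward)


def max_pool2d(x: Tensor, kernel: int = 2, stride: int | None = None, padding: int = 0) -> Tensor:
    stride = stride or kernel
    B, C, H, W = x.shape
    xp = np.pad(
        x.data,
        ((0, 0), (0, 0), (padding, padding), (padding, padding)),
        constant_values=-np.inf,
    )
    view = _im2col_view(xp, kernel, kernel, stride)
    Hp, Wp = view.shape[4], view.shape[5]
    flat = np.ascontiguousarray(view).reshape(B, C, kernel * kernel, Hp, Wp)
    idx = flat.argmax(axis=2)
    out = Tensor(np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0])

    def backward(g):
        gcols = np.zeros_like(flat)
        np.put_along_axis(gcols, idx[:, :, None], g[:, :, None], axis=2)
        gcols6 = gcols.reshape(B, C, kernel, kernel, Hp, Wp)
        x._accumulate(
            _col2im(gcols6, x.shape, kernel, kernel, stride, padding).astype(
                x.data.dtype, copy=False
            )
        )

    return Tensor._track(out, (x,), backward)


def pixel_shuffle(x: Tensor, scale: int) -> Tensor:
    """Rearrange (B, C·r², H, W) → (B, C, H·r, W·r); out[c, rh+i, rw+j] = in[c·r²+i·r+j, h, w]."""
    B, Cr2, H, W = x.shape
    r = scale
    if Cr2 % (r * r):
        raise ValueError(f"channels {Cr2} not divisible by scale² = {r * r}")
    C = Cr2 // (r * r)
    out_data = (
        x.data.reshape(B, C, r, r, H, W).transpose(0, 1, 4, 2, 5, 3).reshape(B, C, H * r, W * r)
    )
    out = Tensor(out_data)

    def backward(g):
        gx = g.reshape(B, C, H, r, W, r).transpose(0, 1, 3, 5, 2, 4).reshape(B, Cr2, H, W)
        x._accumulate(gx)

    return Tensor._track(out, (x,), backward)
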