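"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine implements exactly the primitives the staining networks need:
broadcast arithmetic, matmul, 3x3/1x1 convolutions (im2col + GEMM), 2x2 max
pooling, factor-2 bilinear upsampling, channel concatenation and elementwise
nonlinearities.  Gradients are accumulated on leaf tensors by a topological
backward sweep.  Float32 is the working precision for models; ops preserve
the input dtype so loss formulas can be evaluated in float64 when checked
against closed forms.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        # Copy-on-first-write pins the gradient dtype to the tensor's dtype and
        # guarantees shared upstream buffers are never mutated by `+=`.
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(grad)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
                # free graph references eagerly
                t._backward = None
                t._parents = ()

    # -- basic properties -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _coerce(self, other) -> "Tensor":
        """Wrap `other`; python scalars adopt this tensor's dtype."""
        if isinstance(other, Tensor):
            return other
        if isinstance(other, (int, float)):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(np.asarray(other))

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(g * exponent * a.data ** (exponent - 1))

        return Tensor._make(a.data**exponent, (a,), bwd)

    def matmul(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    __matmul__ = matmul

    # -- reductions / reshapes -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bwd(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def bwd(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return Tensor._make(a.data.reshape(*shape), (a,), bwd)

    # -- elementwise nonlinearities ---------------------------------------
    def log(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bwd)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return Tensor._make(out_data, (a,), bwd)

    def abs(self):
        a = self
        sign = np.sign(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * sign)

        return Tensor._make(np.abs(a.data), (a,), bwd)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return Tensor._make(s, (a,), bwd)

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), bwd)

    def leaky_relu(self, slope: float = 0.1):
        a = self
        factor = np.where(a.data > 0, 1.0, slope).astype(a.data.dtype)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * factor)

        return Tensor._make(a.data * factor, (a,), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def where(cond: np.ndarray, x, y) -> Tensor:
    """Elementwise select; no gradient flows through `cond` (a plain array)."""
    x, y = as_tensor(x), as_tensor(y)
    cond = np.asarray(cond, dtype=bool)

    def bwd(g):
        if x.requires_grad:
            x._accum(_unbroadcast(g * cond, x.data.shape))
        if y.requires_grad:
            y._accum(_unbroadcast(g * ~cond, y.data.shape))

    return Tensor._make(np.where(cond, x.data, y.data), (x, y), bwd)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )


# -- spatial ops (NHWC layout: batch, height, width, channel) --------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) on (B, H, W, C) inputs.

    Weights are (k, k, Cin, Cout).  1x1 stride-1 convolutions reduce to a
    single GEMM without any data movement; k x k convolutions use im2col in
    channel-last order so both the forward GEMM and the backward scatter
    need no transposes.
    """
    B, H, W, C = x.data.shape
    k, k2, Ci, O = w.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
    if k == 1 and stride == 1 and pad == 0:
        flat = x.data.reshape(B * H * W, C)
        wmat = w.data.reshape(C, O)
        out = flat @ wmat
        if b is not None:
            out += b.data

        def bwd1(g):
            gmat = g.reshape(B * H * W, O)
            if w.requires_grad:
                w._accum((flat.T @ gmat).reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accum(gmat.sum(axis=0))
            if x.requires_grad:
                x._accum((gmat @ wmat.T).reshape(x.data.shape))

        parents = (x, w) if b is None else (x, w, b)
        return Tensor._make(out.reshape(B, H, W, O), parents, bwd1)

    if pad:
        xp = np.zeros((B, H + 2 * pad, W + 2 * pad, C), dtype=x.data.dtype)
        xp[:, pad : pad + H, pad : pad + W] = x.data
    else:
        xp = x.data
    Ho = (H + 2 * pad - k) // stride + 1
    Wo = (W + 2 * pad - k) // stride + 1
    # (B, Ho, Wo, k, k, C) im2col built by k*k contiguous-ish slice copies
    cols6 = np.empty((B, Ho, Wo, k, k, C), dtype=x.data.dtype)
    for i in range(k):
        for j in range(k):
            cols6[:, :, :, i, j] = xp[:, i : i + stride * Ho : stride, j : j + stride * Wo : stride]
    cols = cols6.reshape(B * Ho * Wo, k * k * C)
    wmat = w.data.reshape(k * k * C, O)
    out = cols @ wmat
    if b is not None:
        out += b.data

    def bwd(g):
        gmat = g.reshape(B * Ho * Wo, O)
        if w.requires_grad:
            w._accum((cols.T @ gmat).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=0))
        if not x.requires_grad:
            return
        if stride == 1 and k == 2 * pad + 1:
            # dx = correlation of g with the 180-degree-rotated, transposed
            # kernel: one im2col of g plus a GEMM, no scatter pass
            gp = np.zeros((B, Ho + 2 * pad, Wo + 2 * pad, O), dtype=g.dtype)
            gp[:, pad : pad + Ho, pad : pad + Wo] = g.reshape(B, Ho, Wo, O)
            gcols = np.empty((B, H, W, k, k, O), dtype=g.dtype)
            for i in range(k):
                for j in range(k):
                    gcols[:, :, :, i, j] = gp[:, i : i + H, j : j + W]
            wrot = w.data[::-1, ::-1].transpose(0, 1, 3, 2).reshape(k * k * O, C)
            x._accum(
                (gcols.reshape(B * H * W, k * k * O) @ wrot).reshape(x.data.shape)
            )
        else:
            dcols = (gmat @ wmat.T).reshape(B, Ho, Wo, k, k, C)
            dxp = np.zeros((B, H + 2 * pad, W + 2 * pad, C), dtype=x.data.dtype)
            for i in range(k):
                for j in range(k):
                    dxp[:, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += dcols[
                        :, :, :, i, j
                    ]
            x._accum(dxp[:, pad : pad + H, pad : pad + W] if pad else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out.reshape(B, Ho, Wo, O), parents, bwd)


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2, on (B, H, W, C)."""
    B, H, W, C = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2d requires even spatial dimensions")
    quads = (
        x.data[:, 0::2, 0::2],
        x.data[:, 0::2, 1::2],
        x.data[:, 1::2, 0::2],
        x.data[:, 1::2, 1::2],
    )
    out = np.maximum(np.maximum(quads[0], quads[1]), np.maximum(quads[2], quads[3]))

    def bwd(g):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        taken = np.zeros(out.shape, dtype=bool)
        targets = (
            dx[:, 0::2, 0::2], dx[:, 0::2, 1::2], dx[:, 1::2, 0::2], dx[:, 1::2, 1::2]
        )
        for q, t in zip(quads, targets):
            hit = (q == out) & ~taken  # first-match tie break
            t += g * hit
            taken |= hit
        x._accum(dx)

    return Tensor._make(out, (x,), bwd)


_interp_cache: dict[int, np.ndarray] = {}


def _upsample_matrix(n: int, dtype) -> np.ndarray:
    """(2n x n) factor-2 bilinear interpolation matrix, half-pixel centers."""
    U = _interp_cache.get(n)
    if U is None:
        U = np.zeros((2 * n, n))
        src = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
        lo = np.clip(np.floor(src).astype(int), 0, n - 1)
        hi = np.clip(lo + 1, 0, n - 1)
        t = np.clip(src - lo, 0.0, 1.0)
        U[np.arange(2 * n), lo] += 1.0 - t
        U[np.arange(2 * n), hi] += t
        _interp_cache[n] = U
    return U.astype(dtype, copy=False)


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Factor-2 bilinear upsampling on (B, H, W, C), half-pixel alignment."""
    B, H, W, C = x.data.shape
    Uh = _upsample_matrix(H, x.data.dtype)
    Uw = _upsample_matrix(W, x.data.dtype)
    t1 = (Uh @ x.data.reshape(B, H, W * C)).reshape(B * 2 * H, W, C)
    out = (Uw @ t1).reshape(B, 2 * H, 2 * W, C)

    def bwd(g):
        if x.requires_grad:
            g1 = (Uw.T @ g.reshape(B * 2 * H, 2 * W, C)).reshape(B, 2 * H, W * C)
            x._accum((Uh.T @ g1).reshape(B, H, W, C))

    return Tensor._make(out, (x,), bwd)
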