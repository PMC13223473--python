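"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package trains volumetric segmentation networks on CPU, so the compute
core is a small, explicit tape: a :class:`Tensor` wraps an ``ndarray`` and
records a backward closure per operation.  Only the operations the network
needs exist (broadcast arithmetic, matmul, activations, reductions, shape
ops, and N-d convolution via im2col), each with an exact adjoint.

Gradients accumulate in ``Tensor.grad`` after calling :meth:`Tensor.backward`
on a scalar.  ``no_grad()`` disables taping for inference.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

from . import _conv_kernels as _ck

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (adjoint of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev",
                 "_grad_ro")

    # Defer mixed ndarray/Tensor arithmetic to the Tensor operators below
    # (otherwise NumPy would broadcast a Tensor elementwise as an object).
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev
        self._grad_ro = False

    # -- basic protocol ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- graph bookkeeping -------------------------------------------------
    def _accum(self, g: np.ndarray):
        """Accumulate a gradient that may alias another array (copied)."""
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float32, copy=True)
            self._grad_ro = False
        else:
            if self._grad_ro:
                self.grad = self.grad + g
                self._grad_ro = False
            else:
                self.grad += g

    def _accum_own(self, g: np.ndarray):
        """Accumulate a freshly allocated gradient (ownership transferred)."""
        if self.grad is None:
            self.grad = g
            self._grad_ro = False
        elif self._grad_ro:
            self.grad = self.grad + g
            self._grad_ro = False
        else:
            self.grad += g

    def _accum_ref(self, g: np.ndarray):
        """Accumulate a gradient passed through unchanged from downstream.

        The array may be shared with other tensors (or be a view), so it is
        stored by reference and flagged copy-on-write: any later
        accumulation replaces it with a fresh sum instead of mutating it."""
        if self.grad is None:
            self.grad = g
            self._grad_ro = True
        elif self._grad_ro:
            self.grad = self.grad + g
            self._grad_ro = False
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topological sort (graphs can be deep)
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            node._backward = None  # free closures as we go
            node._prev = ()

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        out = _make(self.data + other.data, (self, other))
        if out._prev:
            def bwd(g, a=self, b=other):
                if a.requires_grad or a._prev:
                    ga = _unbroadcast(g, a.data.shape)
                    a._accum_ref(ga) if ga is g else a._accum_own(ga)
                if b.requires_grad or b._prev:
                    gb = _unbroadcast(g, b.data.shape)
                    b._accum_ref(gb) if gb is g else b._accum_own(gb)
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out._prev:
            out._backward = lambda g, a=self: a._accum_own(-g)
        return out

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        out = _make(self.data * other.data, (self, other))
        if out._prev:
            def bwd(g, a=self, b=other):
                if a.requires_grad or a._prev:
                    a._accum_own(_unbroadcast(g * b.data, a.data.shape))
                if b.requires_grad or b._prev:
                    b._accum_own(_unbroadcast(g * a.data, b.data.shape))
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        out = _make(self.data / other.data, (self, other))
        if out._prev:
            def bwd(g, a=self, b=other):
                if a.requires_grad or a._prev:
                    a._accum_own(_unbroadcast(g / b.data, a.data.shape))
                if b.requires_grad or b._prev:
                    b._accum_own(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))
            out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, p: float):
        out = _make(self.data ** p, (self,))
        if out._prev:
            out._backward = lambda g, a=self: a._accum_own(g * p * a.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = astensor(other)
        out = _make(self.data @ other.data, (self, other))
        if out._prev:
            def bwd(g, a=self, b=other):
                if a.requires_grad or a._prev:
                    a._accum_own(g @ b.data.T)
                if b.requires_grad or b._prev:
                    b._accum_own(a.data.T @ g)
            out._backward = bwd
        return out

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out._prev:
            out._backward = lambda g, a=self: a._accum_ref(g.reshape(a.data.shape))
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out._prev:
            basic = isinstance(idx, (int, slice)) or (
                isinstance(idx, tuple)
                and all(isinstance(i, (int, slice)) for i in idx))
            def bwd(g, a=self, idx=idx, basic=basic):
                full = np.zeros_like(a.data)
                if basic:  # basic indexing never aliases, direct add suffices
                    full[idx] += g
                else:
                    np.add.at(full, idx, g)
                a._accum_own(full)
            out._backward = bwd
        return out

    # -- pointwise nonlinearities ---------------------------------------------
    def relu(self):
        out = _make(np.maximum(self.data, 0.0), (self,))
        if out._prev:
            out._backward = lambda g, a=self: a._accum_own(g * (a.data > 0))
        return out

    def sigmoid(self):
        x = self.data
        s = np.empty_like(x)
        pos = x >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        s[~pos] = ex / (1.0 + ex)
        out = _make(s, (self,))
        if out._prev:
            out._backward = lambda g, a=self, s=s: a._accum_own(g * s * (1.0 - s))
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out._prev:
            out._backward = lambda g, a=self: a._accum_own(g / a.data)
        return out

    def exp(self):
        e = np.exp(self.data)
        out = _make(e, (self,))
        if out._prev:
            out._backward = lambda g, a=self, e=e: a._accum_own(g * e)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through only inside the window."""
        out = _make(np.clip(self.data, lo, hi), (self,))
        if out._prev:
            mask = (self.data >= lo) & (self.data <= hi)
            out._backward = lambda g, a=self, m=mask: a._accum_own(g * m)
        return out

    # -- reductions -------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._prev:
            def bwd(g, a=self, axis=axis, keepdims=keepdims):
                if axis is None:
                    a._accum_ref(np.broadcast_to(g, a.data.shape))
                else:
                    if not keepdims:
                        g = np.expand_dims(g, axis)
                    a._accum_ref(np.broadcast_to(g, a.data.shape))
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis, keepdims: bool = False):
        m = self.data.max(axis=axis, keepdims=True)
        out_data = m if keepdims else np.squeeze(m, axis=axis)
        out = _make(out_data, (self,))
        if out._prev:
            mask = (self.data == m)
            counts = mask.sum(axis=axis, keepdims=True)
            def bwd(g, a=self, axis=axis, keepdims=keepdims, mask=mask, counts=counts):
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum_own(mask * (g / counts))
            out._backward = bwd
        return out


def _make(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    """Wrap an array; keep parents only if taping is on and someone needs grads."""
    if _GRAD_ENABLED and any(p.requires_grad or p._prev for p in parents):
        return Tensor(data, _prev=tuple(parents))
    return Tensor(data)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._prev:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)
        def bwd(g, tensors=tensors, offsets=offsets, axis=axis):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad or t._prev:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum_ref(g[tuple(sl)])
        out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Convolution (N, C, D, H, W) via im2col.  Supports dilation and groups; the
# im2col buffer is rebuilt in the backward pass instead of being retained, so
# peak memory stays near a single buffer.
# ---------------------------------------------------------------------------

def _triple(v):
    if isinstance(v, (tuple, list)):
        return tuple(int(x) for x in v)
    return (int(v),) * 3


#: im2col buffers are bounded to roughly this many float32 elements; larger
#: workloads are processed in output-depth chunks to keep peak memory flat.
_COL_BUDGET = 6_000_000


def _pad_spatial(x: np.ndarray, padding) -> np.ndarray:
    pd, ph, pw = padding
    if pd == ph == pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))


def _cols_slab(xp: np.ndarray, ksize, dilation, z0: int, z1: int):
    """im2col over one padded sample for output depth range [z0, z1);
    returns (C*kd*kh*kw, rows) with rows = (z1-z0)*oH*oW.

    The (ck, rows) layout keeps the innermost copy axis contiguous in the
    source and makes the convolution GEMM emit channels-first output with
    no further transpose."""
    kd, kh, kw = ksize
    dd, dh, dw = dilation
    c, Dp, Hp, Wp = xp.shape[1:]
    oH = Hp - dh * (kh - 1)
    oW = Wp - dw * (kw - 1)
    slab = xp[0, :, z0:z1 - 1 + dd * (kd - 1) + 1]
    s = slab.strides
    shape = (c, kd, kh, kw, z1 - z0, oH, oW)
    strides = (s[0], s[1] * dd, s[2] * dh, s[3] * dw, s[1], s[2], s[3])
    cols = np.lib.stride_tricks.as_strided(slab, shape=shape, strides=strides)
    return np.ascontiguousarray(cols).reshape(c * kd * kh * kw,
                                              (z1 - z0) * oH * oW)


def _depth_chunks(oD, oH, oW, ncols):
    step = max(1, min(oD, _COL_BUDGET // max(1, oH * oW * ncols)))
    for z0 in range(0, oD, step):
        yield z0, min(z0 + step, oD)


def _conv3d_forward(x: np.ndarray, w: np.ndarray, b, dilation, padding, groups):
    n, cin, D, H, W = x.shape
    cout = w.shape[0]
    kd, kh, kw = w.shape[2:]
    dd, dh, dw = dilation
    oD = D + 2 * padding[0] - dd * (kd - 1)
    oH = H + 2 * padding[1] - dh * (kh - 1)
    oW = W + 2 * padding[2] - dw * (kw - 1)
    cig = cin // groups
    cog = cout // groups
    if _ck.HAVE_NUMBA:
        xp = np.ascontiguousarray(_pad_spatial(x, padding), dtype=np.float32)
        y = np.zeros((n, cout, oD, oH, oW), dtype=np.float32)
        _ck.conv3d_fwd(xp, np.ascontiguousarray(w, dtype=np.float32), y,
                       dd, dh, dw, cig, cog)
        if b is not None:
            y += b.reshape(1, -1, 1, 1, 1)
        return y
    y = np.empty((n, cout, oD, oH, oW), dtype=np.float32)
    for g in range(groups):
        xp = _pad_spatial(x[:, g * cig:(g + 1) * cig], padding)
        wg = w[g * cog:(g + 1) * cog].reshape(cog, -1)
        for ni in range(n):
            for z0, z1 in _depth_chunks(oD, oH, oW, cig * kd * kh * kw):
                cols = _cols_slab(xp[ni:ni + 1], (kd, kh, kw), dilation, z0, z1)
                out = wg @ cols  # (cog, rows)
                y[ni, g * cog:(g + 1) * cog, z0:z1] = out.reshape(
                    cog, z1 - z0, oH, oW)
    if b is not None:
        y += b.reshape(1, -1, 1, 1, 1)
    return y


def _conv3d_input_grad(gy: np.ndarray, w: np.ndarray, x_shape, dilation, padding, groups):
    """dL/dx as a convolution of gy with the spatially flipped kernel."""
    kd, kh, kw = w.shape[2:]
    dd, dh, dw = dilation
    # full-correlation padding so output matches x spatially (stride 1)
    fp = (dd * (kd - 1) - padding[0], dh * (kh - 1) - padding[1], dw * (kw - 1) - padding[2])
    cin = x_shape[1]
    cout = w.shape[0]
    cig = cin // groups
    cog = cout // groups
    # flipped kernel, swapped in/out channel roles per group
    wf = w[:, :, ::-1, ::-1, ::-1]
    grads = []
    for g in range(groups):
        wg = wf[g * cog:(g + 1) * cog]            # (cog, cig, k, k, k)
        wswap = wg.transpose(1, 0, 2, 3, 4)        # (cig, cog, k, k, k)
        gyg = gy[:, g * cog:(g + 1) * cog]
        grads.append(_conv3d_forward(gyg, np.ascontiguousarray(wswap), None,
                                     dilation, fp, 1))
    return np.concatenate(grads, axis=1)


def _conv3d_weight_grad(x: np.ndarray, gy: np.ndarray, w_shape, dilation, padding, groups):
    n = x.shape[0]
    cout, cig, kd, kh, kw = w_shape
    cog = cout // groups
    oD, oH, oW = gy.shape[2:]
    if _ck.HAVE_NUMBA:
        xp = np.ascontiguousarray(_pad_spatial(x, padding), dtype=np.float32)
        dwt = np.zeros(w_shape, dtype=np.float32)
        _ck.conv3d_wgrad(xp, np.ascontiguousarray(gy, dtype=np.float32), dwt,
                         dilation[0], dilation[1], dilation[2], cig, cog)
        return dwt
    dw = np.zeros((cout, cig * kd * kh * kw), dtype=np.float32)
    for g in range(groups):
        xp = _pad_spatial(x[:, g * cig:(g + 1) * cig], padding)
        for ni in range(n):
            for z0, z1 in _depth_chunks(oD, oH, oW, cig * kd * kh * kw):
                cols = _cols_slab(xp[ni:ni + 1], (kd, kh, kw), dilation, z0, z1)
                gyg = np.ascontiguousarray(
                    gy[ni, g * cog:(g + 1) * cog, z0:z1]).reshape(cog, -1)
                dw[g * cog:(g + 1) * cog] += gyg @ cols.T
    return dw.reshape(w_shape)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           dilation=1, padding=0, groups: int = 1) -> Tensor:
    """Stride-1 3D convolution on (N, C, D, H, W) with dilation and groups."""
    dilation = _triple(dilation)
    padding = _triple(padding)
    parents = (x, weight) if bias is None else (x, weight, bias)
    y = _conv3d_forward(x.data, weight.data,
                        None if bias is None else bias.data,
                        dilation, padding, groups)
    out = _make(y, parents)
    if out._prev:
        def bwd(g, x=x, weight=weight, bias=bias,
                dilation=dilation, padding=padding, groups=groups):
            g = np.ascontiguousarray(g)
            if x.requires_grad or x._prev:
                x._accum_own(_conv3d_input_grad(g, weight.data, x.data.shape,
                                                dilation, padding, groups))
            if weight.requires_grad or weight._prev:
                weight._accum_own(_conv3d_weight_grad(x.data, g, weight.data.shape,
                                                      dilation, padding, groups))
            if bias is not None and (bias.requires_grad or bias._prev):
                bias._accum_own(g.sum(axis=(0, 2, 3, 4)))
        out._backward = bwd
    return out


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None, padding: int = 0) -> Tensor:
    """1D convolution on (N, C, L) expressed through conv3d (length on the W axis)."""
    n, c, L = x.shape
    x5 = x.reshape(n, c, 1, 1, L)
    k = weight.shape[-1]
    w5 = weight.reshape(weight.shape[0], weight.shape[1], 1, 1, k)
    y = conv3d(x5, w5, bias, dilation=1, padding=(0, 0, padding), groups=1)
    return y.reshape(n, y.shape[1], y.shape[-1])


def maxpool3d_2(x: Tensor) -> Tensor:
    """2x2x2 max pooling; all spatial dims must be even."""
    n, c, D, H, W = x.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"maxpool3d_2 requires even spatial dims, got {(D, H, W)}")
    xr = x.reshape(n, c, D // 2, 2, H // 2, 2, W // 2, 2)
    return xr.max(axis=7).max(axis=5).max(axis=3)


def batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float,
                    axes=(0, 2, 3, 4)):
    """Fused training-mode batch normalization over ``axes``.

    Computing the whole normalization as one taped op (with the standard
    closed-form backward) keeps the graph from retaining half a dozen
    full-size intermediates per call.  Returns ``(out, mean, var)`` with the
    batch statistics as flat per-channel arrays for running-stat updates.
    """
    xd = x.data
    mean = xd.mean(axis=axes, keepdims=True)
    var = ((xd - mean) ** 2).mean(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xn = (xd - mean) * inv
    cshape = tuple(1 if i in axes else s for i, s in enumerate(xd.shape))
    y = gamma.data.reshape(cshape) * xn + beta.data.reshape(cshape)
    out = _make(y, (x, gamma, beta))
    if out._prev:
        def bwd(g, x=x, gamma=gamma, beta=beta, xn=xn, inv=inv,
                cshape=cshape, axes=axes):
            if beta.requires_grad or beta._prev:
                beta._accum_own(g.sum(axis=axes))
            if gamma.requires_grad or gamma._prev:
                gamma._accum_own((g * xn).sum(axis=axes))
            if x.requires_grad or x._prev:
                gxn = g * gamma.data.reshape(cshape)
                t1 = gxn.mean(axis=axes, keepdims=True)
                t2 = (gxn * xn).mean(axis=axes, keepdims=True)
                gxn -= t1
                gxn -= xn * t2
                gxn *= inv
                x._accum_own(gxn)
        out._backward = bwd
    return out, mean.reshape(-1), var.reshape(-1)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Linear-interpolation matrix for resizing a single axis (corner-agnostic)."""
    A = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        t = src - lo
        A[i, lo] += 1.0 - t
        A[i, hi] += t
    return A


def _apply_axis_matrix(x: np.ndarray, A: np.ndarray, axis: int) -> np.ndarray:
    moved = np.moveaxis(x, axis, -1)
    out = moved @ A.T
    return np.moveaxis(out, -1, axis)


def upsample_trilinear_2(x: Tensor) -> Tensor:
    """Trilinear 2x upsampling of (N, C, D, H, W)."""
    n, c, D, H, W = x.shape
    mats = [_interp_matrix(2 * s, s) for s in (D, H, W)]
    y = x.data
    for ax, A in zip((2, 3, 4), mats):
        y = _apply_axis_matrix(y, A, ax)
    out = _make(np.ascontiguousarray(y), (x,))
    if out._prev:
        def bwd(g, x=x, mats=mats):
            for ax, A in zip((4, 3, 2), reversed(mats)):
                g = _apply_axis_matrix(g, A.T, ax)
            x._accum_own(np.ascontiguousarray(g))
        out._backward = bwd
    return out
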