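"""Minimal reverse-mode automatic differentiation engine and neural layers.

Everything runs on numpy float32 arrays in NCHW layout.  The engine is
tape-based: each op returns a :class:`Tensor` holding a backward closure, and
``Tensor.backward()`` walks the tape in reverse topological order.  Only the
primitives the change-detection network needs are implemented: convolution
(via im2col + BLAS matmul), batch normalization, bilinear resampling, pooling,
a one-level orthonormal Haar transform pair, and the usual pointwise ops.

Multiply-accumulate (MAC) counting for complexity reports is built into the
three dense primitives (conv2d, linear, matmul) behind the
:func:`count_macs` context manager; pointwise ops, normalization, pooling and
resampling are not counted, matching the single-count MAC convention of the
common FLOP counters.
"""

from __future__ import annotations

import contextlib
from collections import OrderedDict

import numpy as np
from scipy.special import expit as _expit

# ---------------------------------------------------------------------------
# global switches
# ---------------------------------------------------------------------------

_GRAD_ENABLED = True
_MAC_COUNTER: list | None = None


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev, _GRAD_ENABLED = _GRAD_ENABLED, False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextlib.contextmanager
def count_macs():
    """Context manager yielding a one-element list accumulating MACs."""
    global _MAC_COUNTER
    prev, _MAC_COUNTER = _MAC_COUNTER, [0]
    try:
        yield _MAC_COUNTER
    finally:
        _MAC_COUNTER = prev


def _add_macs(n: int) -> None:
    if _MAC_COUNTER is not None:
        _MAC_COUNTER[0] += int(n)


# ---------------------------------------------------------------------------
# Tensor
# ---------------------------------------------------------------------------


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._prev: tuple = ()
        self.name = name

    # -- plumbing ----------------------------------------------------------
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
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._prev:
                # free intermediate grads eagerly except leaves
                node._backward = None

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, pow_scalar(other, -1.0))
        return mul(self, 1.0 / other)

    def __pow__(self, p):
        return pow_scalar(self, p)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = parents
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# pointwise / reduction primitives
# ---------------------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    if not isinstance(b, Tensor):
        a = as_tensor(a)
        bv = np.float32(b) if np.isscalar(b) else np.asarray(b, np.float32)
        data = a.data * bv

        def backward_const(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * bv, a.shape))

        return _make(data, (a,), backward_const)
    a = as_tensor(a)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def pow_scalar(a, p: float) -> Tensor:
    a = as_tensor(a)
    data = np.power(a.data, p)

    def backward(g):
        if a.requires_grad:
            a._accum(g * p * np.power(a.data, p - 1.0))

    return _make(data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g / a.data)

    return _make(data, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp with pass-through gradient in the interior."""
    a = as_tensor(a)
    data = np.clip(a.data, lo, hi)

    def backward(g):
        if a.requires_grad:
            mask = ((a.data >= lo) & (a.data <= hi)).astype(np.float32)
            a._accum(g * mask)

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    data = np.maximum(a.data, 0.0)

    def backward(g):
        if a.requires_grad:
            a._accum(g * (a.data > 0))

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    data = _expit(a.data).astype(np.float32)

    def backward(g):
        if a.requires_grad:
            a._accum(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def reduce_sum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            gg = g
            if not keepdims and axis is not None:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).astype(np.float32))

    return _make(data, (a,), backward)


def reduce_mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.size if axis is None else np.prod(
        [a.shape[i] for i in np.atleast_1d(axis)]
    )
    return mul(reduce_sum(a, axis, keepdims), 1.0 / float(n))


def reduce_max(a, axis, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.max(axis=axis, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            full = a.data.max(axis=axis, keepdims=True)
            mask = (a.data == full).astype(np.float32)
            mask /= np.maximum(mask.sum(axis=axis, keepdims=True), 1.0)
            gg = g if keepdims or np.ndim(g) == a.ndim else np.expand_dims(g, axis)
            a._accum(mask * gg)

    return _make(data, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accum(g.reshape(a.shape))

    return _make(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accum(g.transpose(inv))

    return _make(data, (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    return _make(data, tensors, backward)


def narrow(a, axis: int, start: int, length: int) -> Tensor:
    """Slice ``length`` entries from ``start`` along ``axis``."""
    a = as_tensor(a)
    idx = [slice(None)] * a.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            full = np.zeros(a.shape, dtype=np.float32)
            full[idx] = g
            a._accum(full)

    return _make(data, (a,), backward)


def matmul(a, b) -> Tensor:
    """Batched matrix multiply (numpy @ semantics on the last two axes)."""
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data
    _add_macs(int(np.prod(data.shape)) * a.shape[-1])

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

    return _make(data, (a, b), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * data).sum(axis=axis, keepdims=True)
            a._accum(data * (g - dot))

    return _make(data, (a,), backward)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    shifted = a.data - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    data = shifted - lse
    sm = np.exp(data)

    def backward(g):
        if a.requires_grad:
            a._accum(g - sm * g.sum(axis=axis, keepdims=True))

    return _make(data, (a,), backward)


# ---------------------------------------------------------------------------
# spatial primitives
# ---------------------------------------------------------------------------


def _pad_nchw(x: np.ndarray, ph: int, pw: int, value: float = 0.0) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)),
                  constant_values=value)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int):
    """Return windows of shape (N, C, Ho, Wo, kh, kw) as a strided view."""
    dkh, dkw = (kh - 1) * dilation + 1, (kw - 1) * dilation + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (dkh, dkw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]
    return win


def _col2im(dcols: np.ndarray, xp_shape, kh, kw, stride, dilation):
    """Scatter (N, C, Ho, Wo, kh, kw) gradients back to padded input shape."""
    N, C, Hp, Wp = xp_shape
    Ho, Wo = dcols.shape[2], dcols.shape[3]
    dxp = np.zeros(xp_shape, dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            hi = i * dilation
            wj = j * dilation
            dxp[:, :, hi:hi + Ho * stride:stride,
                wj:wj + Wo * stride:stride] += dcols[:, :, :, :, i, j]
    return dxp


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0,
           dilation: int = 1, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW input, OIHW weight."""
    x, w = as_tensor(x), as_tensor(w)
    N, C, H, W = x.shape
    O, Cg, kh, kw = w.shape
    if C != Cg * groups:
        raise ValueError(f"conv2d channel mismatch: input {C}, "
                         f"weight expects {Cg * groups}")
    xp = _pad_nchw(x.data, padding, padding)
    win = _im2col(xp, kh, kw, stride, dilation)  # N,C,Ho,Wo,kh,kw
    Ho, Wo = win.shape[2], win.shape[3]
    _add_macs(N * Ho * Wo * O * Cg * kh * kw)

    if groups == 1:
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * Ho * Wo, C * kh * kw)
        wmat = w.data.reshape(O, -1)
        out = (cols @ wmat.T).reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)
    elif groups == C and Cg == 1:
        # depthwise
        out = np.einsum("nchwij,cij->nchw", win, w.data[:, 0],
                        optimize=True)
        cols = None
        wmat = None
    else:
        og = O // groups
        out = np.empty((N, O, Ho, Wo), dtype=np.float32)
        cols = None
        wmat = None
        for g_i in range(groups):
            wi = w.data[g_i * og:(g_i + 1) * og].reshape(og, -1)
            ci = np.ascontiguousarray(
                win[:, g_i * Cg:(g_i + 1) * Cg].transpose(0, 2, 3, 1, 4, 5)
            ).reshape(N * Ho * Wo, Cg * kh * kw)
            out[:, g_i * og:(g_i + 1) * og] = (
                (ci @ wi.T).reshape(N, Ho, Wo, og).transpose(0, 3, 1, 2))
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)
    out = np.ascontiguousarray(out, dtype=np.float32)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, O)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if groups == 1:
            c = cols if cols is not None else np.ascontiguousarray(
                win.transpose(0, 2, 3, 1, 4, 5)).reshape(N * Ho * Wo, -1)
            if w.requires_grad:
                w._accum((gmat.T @ c).reshape(w.shape))
            if x.requires_grad:
                dcols = (gmat @ w.data.reshape(O, -1)).reshape(
                    N, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
                dxp = _col2im(dcols, xp.shape, kh, kw, stride, dilation)
                dx = dxp[:, :, padding:padding + H, padding:padding + W]
                x._accum(np.ascontiguousarray(dx))
        elif groups == C and Cg == 1:
            if w.requires_grad:
                dw = np.einsum("nchwij,nchw->cij", win, g, optimize=True)
                w._accum(dw[:, None])
            if x.requires_grad:
                dcols = g[:, :, :, :, None, None] * w.data[:, 0][None, :, None,
                                                                 None]
                dxp = _col2im(dcols, xp.shape, kh, kw, stride, dilation)
                x._accum(np.ascontiguousarray(
                    dxp[:, :, padding:padding + H, padding:padding + W]))
        else:
            og = O // groups
            dxp = np.zeros(xp.shape, dtype=np.float32) if x.requires_grad \
                else None
            for g_i in range(groups):
                gi = g[:, g_i * og:(g_i + 1) * og].transpose(0, 2, 3, 1
                                                             ).reshape(-1, og)
                ci = np.ascontiguousarray(
                    win[:, g_i * Cg:(g_i + 1) * Cg].transpose(0, 2, 3, 1, 4, 5)
                ).reshape(N * Ho * Wo, Cg * kh * kw)
                if w.requires_grad:
                    dw = (gi.T @ ci).reshape(og, Cg, kh, kw)
                    if w.grad is None:
                        w.grad = np.zeros(w.shape, dtype=np.float32)
                    w.grad[g_i * og:(g_i + 1) * og] += dw
                if dxp is not None:
                    wi = w.data[g_i * og:(g_i + 1) * og].reshape(og, -1)
                    dcols = (gi @ wi).reshape(N, Ho, Wo, Cg, kh, kw
                                              ).transpose(0, 3, 1, 2, 4, 5)
                    dxp[:, g_i * Cg:(g_i + 1) * Cg] += _col2im(
                        dcols, (N, Cg, xp.shape[2], xp.shape[3]),
                        kh, kw, stride, dilation)
            if dxp is not None:
                x._accum(np.ascontiguousarray(
                    dxp[:, :, padding:padding + H, padding:padding + W]))

    return _make(out, (x, w) + ((b,) if b is not None else ()), backward)


def linear(x, w, b=None) -> Tensor:
    """x: (..., in) @ w.T with w: (out, in)."""
    x, w = as_tensor(x), as_tensor(w)
    _add_macs(int(np.prod(x.shape[:-1])) * w.shape[0] * w.shape[1])
    data = x.data @ w.data.T
    if b is not None:
        data = data + b.data

    def backward(g):
        if w.requires_grad:
            gm = g.reshape(-1, w.shape[0])
            xm = x.data.reshape(-1, w.shape[1])
            w._accum(gm.T @ xm)
        if b is not None and b.requires_grad:
            b._accum(g.reshape(-1, w.shape[0]).sum(axis=0))
        if x.requires_grad:
            x._accum(g @ w.data)

    return _make(data, (x, w) + ((b,) if b is not None else ()), backward)


def max_pool2d(x, kernel: int, stride: int, padding: int = 0) -> Tensor:
    x = as_tensor(x)
    N, C, H, W = x.shape
    xp = _pad_nchw(x.data, padding, padding, value=-np.inf)
    win = _im2col(xp, kernel, kernel, stride, 1)
    N_, C_, Ho, Wo = win.shape[:4]
    flat = win.reshape(N, C, Ho, Wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dxp = np.zeros(xp.shape, dtype=np.float32)
        ki, kj = np.divmod(arg, kernel)
        n_i, c_i, ho_i, wo_i = np.indices((N, C, Ho, Wo), sparse=False)
        rows = ho_i * stride + ki
        cols = wo_i * stride + kj
        np.add.at(dxp, (n_i, c_i, rows, cols), g)
        x._accum(np.ascontiguousarray(
            dxp[:, :, padding:padding + H, padding:padding + W]))

    return _make(data, (x,), backward)


def global_avg_pool(x, keepdims: bool = True) -> Tensor:
    return reduce_mean(x, axis=(2, 3), keepdims=keepdims)


def global_max_pool(x, keepdims: bool = True) -> Tensor:
    return reduce_max(x, axis=(2, 3), keepdims=keepdims)


def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (align_corners=False)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    w = (src - lo).astype(np.float32)
    m[np.arange(n_out), lo] += 1.0 - w
    m[np.arange(n_out), hi] += w
    return m


_RESIZE_CACHE: dict = {}


def _resize_mat_cached(n_in, n_out):
    key = (n_in, n_out)
    if key not in _RESIZE_CACHE:
        _RESIZE_CACHE[key] = _resize_matrix(n_in, n_out)
    return _RESIZE_CACHE[key]


def interpolate_bilinear(x, out_hw) -> Tensor:
    """Bilinear resize of an NCHW tensor (align_corners=False)."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    Ho, Wo = out_hw
    if (H, W) == (Ho, Wo):
        return x
    R = _resize_mat_cached(H, Ho)
    S = _resize_mat_cached(W, Wo)
    data = np.einsum("nchw,oh,pw->ncop", x.data, R, S, optimize=True)

    def backward(g):
        if x.requires_grad:
            x._accum(np.einsum("ncop,oh,pw->nchw", g, R, S, optimize=True))

    return _make(np.ascontiguousarray(data, dtype=np.float32), (x,), backward)


# one-level orthonormal Haar transform (used by the wavelet conv block)

_HAAR = 0.5 * np.array(
    [[[1, 1], [1, 1]],     # LL
     [[1, -1], [1, -1]],   # LH
     [[1, 1], [-1, -1]],   # HL
     [[1, -1], [-1, 1]]],  # HH
    dtype=np.float32)


def _haar_fwd(x: np.ndarray) -> np.ndarray:
    N, C, H, W = x.shape
    blocks = x.reshape(N, C, H // 2, 2, W // 2, 2)
    return np.einsum("nchiwj,sij->nschw", blocks, _HAAR,
                     optimize=True).reshape(N, 4 * C, H // 2, W // 2)


def _haar_inv(y: np.ndarray) -> np.ndarray:
    N, C4, Hh, Wh = y.shape
    C = C4 // 4
    ys = y.reshape(N, 4, C, Hh, Wh)
    blocks = np.einsum("nschw,sij->nchiwj", ys, _HAAR, optimize=True)
    return np.ascontiguousarray(blocks.reshape(N, C, 2 * Hh, 2 * Wh))


def haar_decompose(x) -> Tensor:
    """(N,C,H,W) -> (N,4C,H/2,W/2) orthonormal sub-bands [LL,LH,HL,HH]."""
    x = as_tensor(x)
    if x.shape[2] % 2 or x.shape[3] % 2:
        raise ValueError("haar_decompose requires even spatial dims")
    data = _haar_fwd(x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(_haar_inv(g))

    return _make(data, (x,), backward)


def haar_reconstruct(y) -> Tensor:
    y = as_tensor(y)
    data = _haar_inv(y.data)

    def backward(g):
        if y.requires_grad:
            y._accum(_haar_fwd(g))

    return _make(data, (y,), backward)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters ignore the no_grad flag at init


class Module:
    """Torch-like container: tracks sub-modules, parameters and buffers."""

    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, key, value):
        if isinstance(value, Parameter):
            self._params[key] = value
        elif isinstance(value, Module):
            self._modules[key] = value
        object.__setattr__(self, key, value)

    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield f"{prefix}{k}", p
        for k, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{k}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for k, b in self._buffers.items():
            yield f"{prefix}{k}", b
        for k, m in self._modules.items():
            yield from m.named_buffers(f"{prefix}{k}.")

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        state.update({f"buf:{k}": b.copy() for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        for k, p in self.named_parameters():
            p.data = np.asarray(state[k], dtype=np.float32).reshape(p.shape)
        bufs = dict(self.named_buffers())
        for k, b in bufs.items():
            key = f"buf:{k}"
            if key in state:
                b[...] = np.asarray(state[key], dtype=b.dtype).reshape(b.shape)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming(rng: np.random.Generator, shape, fan_out: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_out)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, rng, cin, cout, kernel, stride=1, padding=0,
                 dilation=1, groups=1, bias=False):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.dilation, self.groups = dilation, groups
        fan_out = cout * kernel * kernel // groups
        self.weight = Parameter(
            _kaiming(rng, (cout, cin // groups, kernel, kernel), fan_out))
        self.bias = Parameter(np.zeros(cout, np.float32)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.dilation, self.groups)


class Linear(Module):
    def __init__(self, rng, fin, fout, bias=True):
        super().__init__()
        bound = 1.0 / np.sqrt(fin)
        self.weight = Parameter(
            rng.uniform(-bound, bound, (fout, fin)).astype(np.float32))
        self.bias = Parameter(np.zeros(fout, np.float32)) if bias else None

    def forward(self, x):
        return linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Batch normalization over (N,H,W) per channel with running statistics."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(c, np.float32))
        self.bias = Parameter(np.zeros(c, np.float32))
        self._buffers["running_mean"] = np.zeros(c, np.float32)
        self._buffers["running_var"] = np.ones(c, np.float32)

    def forward(self, x):
        w = reshape(self.weight, (1, -1, 1, 1))
        b = reshape(self.bias, (1, -1, 1, 1))
        if self.training:
            mu = reduce_mean(x, axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = reduce_mean(mul(xc, xc), axis=(0, 2, 3), keepdims=True)
            rm = self._buffers["running_mean"]
            rv = self._buffers["running_var"]
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var.data.reshape(-1) * n / max(n - 1, 1)
            rm += self.momentum * (mu.data.reshape(-1) - rm)
            rv += self.momentum * (unbiased - rv)
            inv = pow_scalar(var + self.eps, -0.5)
            return add(mul(mul(xc, inv), w), b)
        rm = Tensor(self._buffers["running_mean"].reshape(1, -1, 1, 1))
        inv = Tensor(1.0 / np.sqrt(
            self._buffers["running_var"].reshape(1, -1, 1, 1) + self.eps))
        return add(mul(mul(x - rm, inv), w), b)


class ReLU(Module):
    def forward(self, x):
        return relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return sigmoid(x)


class MaxPool2d(Module):
    def __init__(self, kernel, stride, padding=0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class Identity(Module):
    def forward(self, x):
        return x


def conv_bn_relu(rng, cin, cout, kernel, stride=1, dilation=1, groups=1):
    pad = dilation * (kernel // 2)
    return Sequential(
        Conv2d(rng, cin, cout, kernel, stride, pad, dilation, groups),
        BatchNorm2d(cout), ReLU())


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class SGD:
    """SGD with momentum and L2 weight decay (decay folded into the gradient)."""

    def __init__(self, params, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class StepLR:
    """Multiply the learning rate by ``gamma`` every ``step_size`` epochs."""

    def __init__(self, optimizer: SGD, step_size: int, gamma: float):
        self.optimizer = optimizer
        self.step_size, self.gamma = step_size, gamma
        self.base_lr = optimizer.lr
        self.epoch = 0

    def step(self):
        self.epoch += 1
        self.optimizer.lr = self.base_lr * (
            self.gamma ** (self.epoch // self.step_size))

    def lr_at(self, epoch: int) -> float:
        """Learning rate in force during 1-based ``epoch``."""
        return self.base_lr * (self.gamma ** ((epoch - 1) // self.step_size))
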