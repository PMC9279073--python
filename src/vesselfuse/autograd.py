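"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine implements exactly the operations the segmentation network needs:
broadcast arithmetic, matmul, reductions, shape ops, sigmoid/ReLU/log/clip,
2-D convolution (im2col), and separable bilinear/nearest upsampling expressed
as precomputed interpolation matrices.  Graphs are built define-by-run; a
tensor produced while gradients are disabled (or from constant inputs) carries
no graph, so inference costs no extra memory.

Dtype is preserved: float32 in the training path, float64 in gradient-check
tests.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _as_float(data):
    arr = np.asarray(data)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    return arr


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_float(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction of op results ------------------------------------
    @staticmethod
    def _result(data, parents: Sequence["Tensor"], backward):
        track = _grad_enabled and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=track)
        if track:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            g = np.asarray(g)
            # take ownership of freshly allocated arrays; copy views/aliases
            self.grad = g if g.base is None and g.flags.owndata else g.copy()
        else:
            self.grad = self.grad + g if self.grad.base is not None \
                else np.add(self.grad, g, out=self.grad)

    def backward(self, grad=None):
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1).

        Intermediate nodes release their gradient (and their activation
        array) as soon as their backward step has run, so peak memory stays
        close to the size of the forward graph.
        """
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = np.array(grad, dtype=self.data.dtype)  # private copy
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p._backward is not None or p.requires_grad:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._backward is not None:  # intermediate, not a leaf
                node.grad = None
                if node is not self:
                    node.data = None  # consumers' backwards have already run
                node._backward = None
                node._parents = ()

    # -- operator sugar -------------------------------------------------
    # python scalars are wrapped at the tensor's own dtype so float32
    # graphs are not silently promoted to float64
    def __add__(self, other):
        return add(self, _wrap_like(other, self.data.dtype))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap_like(other, self.data.dtype))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, Tensor(np.array(-1.0, dtype=self.data.dtype)))

    def __sub__(self, other):
        return add(self, -_wrap_like(other, self.data.dtype))

    def __rsub__(self, other):
        return add(_wrap_like(other, self.data.dtype), -self)

    def __truediv__(self, other):
        return mul(self, power(_wrap_like(other, self.data.dtype), -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap_like(other, self.data.dtype), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __getitem__(self, idx):
        return getitem(self, idx)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _wrap_like(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if arr.ndim == 0:
        arr = arr.astype(dtype)
    return Tensor(arr)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise / arithmetic
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        given = False
        if a.requires_grad or a._backward:
            ga = _unbroadcast(g, a.data.shape)
            given = ga is g
            a._accumulate(ga)
        if b.requires_grad or b._backward:
            gb = _unbroadcast(g, b.data.shape)
            # never hand the same owned array to two parents
            b._accumulate(gb.copy() if (gb is g and given) else gb)

    return Tensor._result(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad or a._backward:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad or b._backward:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def power(a: Tensor, p: float) -> Tensor:
    a = _wrap(a)
    p = float(p)
    out_data = a.data ** p

    def backward(g):
        a._accumulate(g * (p * a.data ** (p - 1.0)))

    return Tensor._result(out_data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad or a._backward:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad or b._backward:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    x = _wrap(x)
    out_data = np.maximum(x.data, 0)

    def backward(g):
        x._accumulate(g * (x.data > 0))

    return Tensor._result(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = _wrap(x)
    # 1/(1+exp(-x)) saturates to exactly 0/1 on overflow, which is correct
    with np.errstate(over="ignore"):
        out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._result(out_data, (x,), backward)


def log(x: Tensor) -> Tensor:
    """Natural log; caller guarantees positivity (clip first)."""
    x = _wrap(x)
    out_data = np.log(x.data)

    def backward(g):
        x._accumulate(g / x.data)

    return Tensor._result(out_data, (x,), backward)


def clip(x: Tensor, lo: float | None, hi: float | None) -> Tensor:
    x = _wrap(x)
    out_data = np.clip(x.data, lo, hi)

    def backward(g):
        mask = np.ones_like(x.data, dtype=bool)
        if lo is not None:
            mask &= x.data > lo
        if hi is not None:
            mask &= x.data < hi
        x._accumulate(g * mask)

    return Tensor._result(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------------

def _keepdims_shape(shape, axis):
    if axis is None:
        return (1,) * len(shape)
    axes = axis if isinstance(axis, tuple) else (axis,)
    axes = tuple(a % len(shape) for a in axes)
    return tuple(1 if i in axes else s for i, s in enumerate(shape))


def sum_(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = _wrap(x)
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        gk = g.reshape(_keepdims_shape(x.data.shape, axis)) if not keepdims else g
        x._accumulate(np.broadcast_to(gk, x.data.shape))

    return Tensor._result(out_data, (x,), backward)


def mean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = _wrap(x)
    out_data = x.data.mean(axis=axis, keepdims=keepdims)
    count = x.data.size / out_data.size

    def backward(g):
        gk = g.reshape(_keepdims_shape(x.data.shape, axis)) if not keepdims else g
        x._accumulate(np.broadcast_to(gk, x.data.shape) / count)

    return Tensor._result(out_data, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    x = _wrap(x)
    out_data = x.data.reshape(shape)

    def backward(g):
        x._accumulate(g.reshape(x.data.shape))

    return Tensor._result(out_data, (x,), backward)


def transpose(x: Tensor, axes) -> Tensor:
    x = _wrap(x)
    out_data = x.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        x._accumulate(g.transpose(inv))

    return Tensor._result(out_data, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._backward:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._result(out_data, tensors, backward)


def getitem(x: Tensor, idx) -> Tensor:
    x = _wrap(x)
    out_data = x.data[idx]

    def backward(g):
        full = np.zeros_like(x.data)
        full[idx] = g
        x._accumulate(full)

    return Tensor._result(out_data, (x,), backward)


def pad(x: Tensor, pad_width) -> Tensor:
    """Zero padding; pad_width as for np.pad."""
    x = _wrap(x)
    out_data = np.pad(x.data, pad_width)

    def backward(g):
        sl = tuple(slice(lo, g.shape[i] - hi if hi else None)
                   for i, (lo, hi) in enumerate(pad_width))
        x._accumulate(g[sl])

    return Tensor._result(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# fused normalization primitives
# ---------------------------------------------------------------------------
# Composing these from reductions is correct but holds many full-size
# intermediates in the graph; the fused forms keep only the normalized map.

def _norm_backward(g, xhat, invstd, gamma_b, axes):
    """Gradient of x for y = gamma*xhat + beta with xhat=(x-mu)*invstd."""
    m = 1
    for a in axes:
        m *= xhat.shape[a]
    dxhat = g * gamma_b if gamma_b is not None else g
    s1 = dxhat.sum(axis=axes, keepdims=True)
    s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
    return invstd * (dxhat - s1 / m - xhat * s2 / m)


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float
              ) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Batch normalization over (N, H, W) per channel, differentiable through
    the batch statistics.  Returns (y, batch_mean, batch_var) — the statistics
    as plain arrays for running-average updates."""
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    axes = (0, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = np.square(x.data).mean(axis=axes, keepdims=True) - np.square(mu)
    np.maximum(var, 0.0, out=var)
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * invstd
    gamma_b = gamma.data.reshape(1, -1, 1, 1)
    out_data = gamma_b * xhat + beta.data.reshape(1, -1, 1, 1)

    def backward(g):
        if gamma.requires_grad or gamma._backward:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad or beta._backward:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad or x._backward:
            x._accumulate(_norm_backward(g, xhat, invstd, gamma_b, axes))

    out = Tensor._result(out_data, (x, gamma, beta), backward)
    return out, mu.reshape(-1), var.reshape(-1)


def batchnorm_relu(x: Tensor, gamma: Tensor, beta: Tensor, eps: float
                   ) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused BN → ReLU (training mode): one output buffer, xhat recomputed
    in the backward pass from the parent activation."""
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    axes = (0, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = np.square(x.data).mean(axis=axes, keepdims=True) - np.square(mu)
    np.maximum(var, 0.0, out=var)
    invstd = 1.0 / np.sqrt(var + eps)
    gamma_b = gamma.data.reshape(1, -1, 1, 1)
    scale = gamma_b * invstd
    shift = beta.data.reshape(1, -1, 1, 1) - mu * scale
    out_data = x.data * scale
    out_data += shift
    np.maximum(out_data, 0.0, out=out_data)

    def backward(g):
        # xhat recomputed: one extra pass instead of a stored full-size map
        xhat = x.data - mu
        xhat *= invstd
        dy = g * (out_data > 0)
        if gamma.requires_grad or gamma._backward:
            gamma._accumulate((dy * xhat).sum(axis=axes))
        if beta.requires_grad or beta._backward:
            beta._accumulate(dy.sum(axis=axes))
        if x.requires_grad or x._backward:
            x._accumulate(_norm_backward(dy, xhat, invstd, gamma_b, axes))

    out = Tensor._result(out_data, (x, gamma, beta), backward)
    return out, mu.reshape(-1), var.reshape(-1)


def instancenorm(x: Tensor, eps: float) -> Tensor:
    """Normalize each (n, c) plane over its spatial positions (no affine)."""
    x = _wrap(x)
    axes = (2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * invstd

    def backward(g):
        x._accumulate(_norm_backward(g, xhat, invstd, None, axes))

    return Tensor._result(xhat.copy(), (x,), backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, stride: int = 1) -> Tensor:
    """Same-padding 2-D convolution (cross-correlation), NCHW layout.

    x: (N, C, H, W); w: (F, C, k, k) with odd k.  Padding is k//2, so the
    output spatial size is ceil(H/stride) for even H.
    """
    x, w = _wrap(x), _wrap(w)
    n, c, h, wd = x.data.shape
    f, cw, k, k2 = w.data.shape
    if cw != c or k != k2 or k % 2 == 0:
        raise ValueError(
            f"conv2d weight {w.data.shape} incompatible with input {x.data.shape}"
        )
    if k == 1:
        return _conv1x1(x, w, stride)
    # shifted-GEMM scheme: never materializes an im2col matrix.  For each
    # kernel offset (i, j) the padded input is cropped/strided and mixed
    # across channels with one batched GEMM; the k*k partial products
    # accumulate into the output.
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    ho = (h + 2 * p - k) // stride + 1
    wo = (wd + 2 * p - k) // stride + 1

    def shifted(i, j):
        sh = xp[:, :, i:i + stride * (ho - 1) + 1:stride,
                j:j + stride * (wo - 1) + 1:stride]
        return np.ascontiguousarray(sh).reshape(n, c, ho * wo)

    out_flat = np.zeros((n, f, ho * wo), dtype=x.data.dtype)
    tmp = np.empty_like(out_flat)
    for i in range(k):
        for j in range(k):
            np.matmul(w.data[:, :, i, j], shifted(i, j), out=tmp)
            out_flat += tmp
    out_data = out_flat.reshape(n, f, ho, wo)

    def backward(g):
        g2 = g.reshape(n, f, ho * wo)
        if w.requires_grad or w._backward:
            gw = np.empty_like(w.data)
            for i in range(k):
                for j in range(k):
                    prod = np.matmul(g2, shifted(i, j).transpose(0, 2, 1))
                    gw[:, :, i, j] = prod.sum(axis=0)
            w._accumulate(gw)
        if x.requires_grad or x._backward:
            dxp = np.zeros((n, c, h + 2 * p, wd + 2 * p), dtype=x.data.dtype)
            for i in range(k):
                for j in range(k):
                    d = np.matmul(w.data[:, :, i, j].T, g2).reshape(
                        n, c, ho, wo)
                    dxp[:, :, i:i + stride * (ho - 1) + 1:stride,
                        j:j + stride * (wo - 1) + 1:stride] += d
            x._accumulate(dxp[:, :, p:p + h, p:p + wd] if p else dxp)

    return Tensor._result(out_data, (x, w), backward)


def _conv1x1(x: Tensor, w: Tensor, stride: int) -> Tensor:
    """Pointwise convolution as a single channel-mixing GEMM."""
    n, c, h, wd = x.data.shape
    f = w.data.shape[0]
    xs = x.data[:, :, ::stride, ::stride] if stride > 1 else x.data
    ho, wo = xs.shape[2], xs.shape[3]
    w2 = w.data.reshape(f, c)
    flat = xs.reshape(n, c, ho * wo)
    out_data = np.matmul(w2, flat).reshape(n, f, ho, wo)

    def backward(g):
        g2 = g.reshape(n, f, ho * wo)
        if w.requires_grad or w._backward:
            gw = np.einsum("nfs,ncs->fc", g2, flat, optimize=True)
            w._accumulate(gw.reshape(f, c, 1, 1))
        if x.requires_grad or x._backward:
            dxs = np.matmul(w2.T, g2).reshape(n, c, ho, wo)
            if stride > 1:
                dx = np.zeros_like(x.data)
                dx[:, :, ::stride, ::stride] = dxs
            else:
                dx = dxs
            x._accumulate(dx)

    return Tensor._result(out_data, (x, w), backward)


# ---------------------------------------------------------------------------
# upsampling as separable linear maps
# ---------------------------------------------------------------------------

_INTERP_CACHE: dict[tuple, np.ndarray] = {}


def interp_matrix(n_in: int, factor: int, mode: str, dtype=np.float32) -> np.ndarray:
    """(n_in*factor, n_in) 1-D resampling matrix, half-pixel-centred coords."""
    key = (n_in, factor, mode, np.dtype(dtype).str)
    if key in _INTERP_CACHE:
        return _INTERP_CACHE[key]
    n_out = n_in * factor
    mat = np.zeros((n_out, n_in), dtype=dtype)
    for i in range(n_out):
        src = (i + 0.5) / factor - 0.5
        if mode == "nearest":
            mat[i, int(np.clip(np.floor(src + 0.5), 0, n_in - 1))] = 1.0
        elif mode == "bilinear":
            j0 = int(np.floor(src))
            t = src - j0
            j0c = int(np.clip(j0, 0, n_in - 1))
            j1c = int(np.clip(j0 + 1, 0, n_in - 1))
            mat[i, j0c] += 1.0 - t
            mat[i, j1c] += t
        else:
            raise ValueError(f"unknown upsample mode: {mode!r}")
    _INTERP_CACHE[key] = mat
    return mat


def _apply_rows(mat: np.ndarray, x4: np.ndarray) -> np.ndarray:
    """y[n,c,a,w] = sum_h mat[a,h] x4[n,c,h,w] via one large GEMM."""
    n, c, h, w = x4.shape
    flat = x4.reshape(n * c, h, w)
    # (A, H) @ (H, NC*W): transpose to put H first, GEMM, transpose back
    xt = flat.transpose(1, 0, 2).reshape(h, n * c * w)
    yt = mat @ xt
    a = mat.shape[0]
    return yt.reshape(a, n * c, w).transpose(1, 0, 2).reshape(n, c, a, w)


def _apply_cols(mat: np.ndarray, x4: np.ndarray) -> np.ndarray:
    """y[n,c,h,b] = sum_w mat[b,w] x4[n,c,h,w] via one large GEMM."""
    n, c, h, w = x4.shape
    flat = x4.reshape(n * c * h, w)
    return (flat @ mat.T).reshape(n, c, h, mat.shape[0])


def upsample2d(x: Tensor, factor: int, mode: str = "bilinear") -> Tensor:
    """Upsample (N, C, H, W) by an integer factor along both spatial axes."""
    x = _wrap(x)
    n, c, h, w = x.data.shape
    a = interp_matrix(h, factor, mode, x.data.dtype)
    b = interp_matrix(w, factor, mode, x.data.dtype)
    out_data = _apply_cols(b, _apply_rows(a, x.data))

    def backward(g):
        x._accumulate(_apply_cols(b.T, _apply_rows(a.T, g)))

    return Tensor._result(out_data, (x,), backward)
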