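"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the operations the detector needs: elementwise
arithmetic, reductions, reshaping/concatenation, activations, softmax,
2-D convolution (grouped and depthwise), batch normalization, max pooling,
and nearest/bilinear upsampling.  Tensors hold float32 data; gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward` via a
topological sweep of the recorded tape.

Convolution uses ``numpy.lib.stride_tricks.sliding_window_view`` plus
``einsum`` so both the forward and backward passes reduce to dense matrix
contractions.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "neg", "scale", "power",
    "div", "tmaximum", "tminimum", "clamp_min", "arctan",
    "tsum", "tmean", "reshape", "transpose", "concat", "narrow",
    "relu", "silu", "sigmoid", "exp", "log", "softmax",
    "conv2d", "batchnorm2d", "maxpool2d", "pad_replicate",
    "upsample_nearest", "upsample_bilinear",
    "no_grad", "is_grad_enabled",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape recording (inference / auditing)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self.prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self.prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
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
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ergonomic operators -------------------------------------------------
    def __add__(self, other):
        return add(self, other) if isinstance(other, Tensor) else shift(self, other)

    def __radd__(self, other):
        return shift(self, other)

    def __sub__(self, other):
        return sub(self, other) if isinstance(other, Tensor) else shift(self, -other)

    def __mul__(self, other):
        return mul(self, other) if isinstance(other, Tensor) else scale(self, other)

    def __rmul__(self, other):
        return scale(self, other)

    def __neg__(self):
        return neg(self)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def _node(data, parents, backward):
    """Build a result tensor, recording the tape only when needed."""
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(g, b.shape))

    return _node(out_data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def backward(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(-g, b.shape))

    return _node(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        a._accum(_unbroadcast(g * b.data, a.shape))
        b._accum(_unbroadcast(g * a.data, b.shape))

    return _node(out_data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    def backward(g):
        a._accum(-g)

    return _node(-a.data, (a,), backward)


def scale(a: Tensor, s: float) -> Tensor:
    s = float(s)

    def backward(g):
        a._accum(g * s)

    return _node(a.data * s, (a,), backward)


def shift(a: Tensor, c: float) -> Tensor:
    c = float(c)

    def backward(g):
        a._accum(g)

    return _node(a.data + c, (a,), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def backward(g):
        a._accum(_unbroadcast(g / b.data, a.shape))
        b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return _node(out_data, (a, b), backward)


def tmaximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; the (sub)gradient follows the larger operand."""
    mask = a.data >= b.data

    def backward(g):
        a._accum(_unbroadcast(g * mask, a.shape))
        b._accum(_unbroadcast(g * ~mask, b.shape))

    return _node(np.maximum(a.data, b.data), (a, b), backward)


def tminimum(a: Tensor, b: Tensor) -> Tensor:
    mask = a.data <= b.data

    def backward(g):
        a._accum(_unbroadcast(g * mask, a.shape))
        b._accum(_unbroadcast(g * ~mask, b.shape))

    return _node(np.minimum(a.data, b.data), (a, b), backward)


def clamp_min(a: Tensor, lo: float) -> Tensor:
    mask = a.data >= lo

    def backward(g):
        a._accum(g * mask)

    return _node(np.maximum(a.data, lo), (a,), backward)


def arctan(a: Tensor) -> Tensor:
    def backward(g):
        a._accum(g / (1.0 + a.data * a.data))

    return _node(np.arctan(a.data), (a,), backward)


def power(a: Tensor, p: float) -> Tensor:
    p = float(p)
    out_data = a.data ** p

    def backward(g):
        a._accum(g * p * a.data ** (p - 1.0))

    return _node(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.shape))
            return
        gg = g
        if not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accum(np.broadcast_to(gg, a.shape))

    return _node(out_data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return scale(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a: Tensor, shape) -> Tensor:
    orig = a.shape

    def backward(g):
        a._accum(g.reshape(orig))

    return _node(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def backward(g):
        a._accum(g.transpose(inv))

    return _node(a.data.transpose(axes), (a,), backward)


def concat(tensors, axis=1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return _node(out_data, tuple(tensors), backward)


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Slice ``length`` entries along ``axis`` starting at ``start``."""
    sl = [slice(None)] * a.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)

    def backward(g):
        full = np.zeros_like(a.data)
        full[sl] = g
        a._accum(full)

    return _node(a.data[sl], (a,), backward)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def relu(a: Tensor) -> Tensor:
    out_data = np.maximum(a.data, 0.0)

    def backward(g):
        a._accum(g * (a.data > 0))

    return _node(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    # exp overflow at extreme negatives saturates to the correct limit 0
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accum(g * s * (1.0 - s))

    return _node(s, (a,), backward)


def silu(a: Tensor) -> Tensor:
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * s

    def backward(g):
        a._accum(g * (s + a.data * s * (1.0 - s)))

    return _node(out_data, (a,), backward)


def exp(a: Tensor) -> Tensor:
    e = np.exp(a.data)

    def backward(g):
        a._accum(g * e)

    return _node(e, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        a._accum(g / a.data)

    return _node(np.log(a.data), (a,), backward)


def softmax(a: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable softmax (max subtraction) along ``axis``."""
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        a._accum(s * (g - dot))

    return _node(s, (a,), backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _windows(xp: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride][:, :, :ho, :wo]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation of NCHW input with OIKK weights.

    Supports arbitrary channel ``groups`` including the depthwise case
    (groups == C_in, one input channel per filter).
    """
    n, c, h, wdt = x.shape
    cout, cin_g, k, k2 = w.shape
    assert k == k2, "square kernels only"
    assert c == cin_g * groups, (
        f"channel mismatch: input {c}, weight expects {cin_g * groups}")
    assert cout % groups == 0
    ho = (h + 2 * padding - k) // stride + 1
    wo = (wdt + 2 * padding - k) // stride + 1
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    win = _windows(xp, k, stride, ho, wo)  # (N,C,Ho,Wo,k,k)

    if groups == c and cin_g == 1:  # depthwise
        out_data = np.einsum("nchwkl,cjkl->nchw", win, w.data, optimize=True)
        if cout != c:
            raise NotImplementedError("depthwise with channel multiplier > 1")
    elif groups == 1:
        out_data = np.einsum("nchwkl,ockl->nohw", win, w.data, optimize=True)
    else:
        cpg, opg = c // groups, cout // groups
        parts = []
        for g in range(groups):
            parts.append(np.einsum(
                "nchwkl,ockl->nohw",
                win[:, g * cpg:(g + 1) * cpg],
                w.data[g * opg:(g + 1) * opg], optimize=True))
        out_data = np.concatenate(parts, axis=1)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(g):
        # weight gradient
        if groups == c and cin_g == 1:
            dw = np.einsum("nchwkl,nchw->ckl", win, g, optimize=True)[:, None]
        elif groups == 1:
            dw = np.einsum("nchwkl,nohw->ockl", win, g, optimize=True)
        else:
            cpg, opg = c // groups, cout // groups
            dw = np.empty_like(w.data)
            for gi in range(groups):
                dw[gi * opg:(gi + 1) * opg] = np.einsum(
                    "nchwkl,nohw->ockl",
                    win[:, gi * cpg:(gi + 1) * cpg],
                    g[:, gi * opg:(gi + 1) * opg], optimize=True)
        w._accum(dw)
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        # input gradient: scatter k*k shifted contributions
        dxp = np.zeros_like(xp)
        for ky in range(k):
            for kx in range(k):
                if groups == c and cin_g == 1:
                    contrib = g * w.data[None, :, 0, ky, kx, None, None]
                elif groups == 1:
                    contrib = np.einsum("nohw,oc->nchw", g, w.data[:, :, ky, kx],
                                        optimize=True)
                else:
                    cpg, opg = c // groups, cout // groups
                    pieces = []
                    for gi in range(groups):
                        pieces.append(np.einsum(
                            "nohw,oc->nchw",
                            g[:, gi * opg:(gi + 1) * opg],
                            w.data[gi * opg:(gi + 1) * opg, :, ky, kx],
                            optimize=True))
                    contrib = np.concatenate(pieces, axis=1)
                dxp[:, :, ky:ky + stride * ho:stride,
                    kx:kx + stride * wo:stride] += contrib
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accum(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, backward)


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean: np.ndarray, running_var: np.ndarray,
                *, training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, H, W) with affine transform.

    ``running_mean``/``running_var`` are plain arrays updated in place during
    training and used as the statistics in evaluation mode.
    """
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mean
        running_var *= (1.0 - momentum)
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward(g):
        gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        beta._accum(g.sum(axis=(0, 2, 3)))
        gi = g * gamma.data[None, :, None, None]
        if training:
            s1 = gi.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (gi * xhat).sum(axis=(0, 2, 3), keepdims=True)
            dx = (gi - s1 / m - xhat * s2 / m) * inv[None, :, None, None]
        else:
            dx = gi * inv[None, :, None, None]
        x._accum(dx)

    return _node(out_data, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# pooling / resampling
# ---------------------------------------------------------------------------

def maxpool2d(x: Tensor, k: int, *, stride: int = 1, padding: int = 0) -> Tensor:
    n, c, h, w = x.shape
    ho = (h + 2 * padding - k) // stride + 1
    wo = (w + 2 * padding - k) // stride + 1
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    else:
        xp = x.data
    win = _windows(xp, k, stride, ho, wo).reshape(n, c, ho, wo, k * k)
    idx = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dxp = np.zeros_like(xp)
        ky, kx = np.divmod(idx, k)
        ni, ci, oi, oj = np.indices(idx.shape)
        np.add.at(dxp, (ni, ci, oi * stride + ky, oj * stride + kx), g)
        xg = dxp[:, :, padding:h + padding, padding:w + padding] if padding else dxp
        x._accum(xg)

    return _node(out_data, (x,), backward)


def pad_replicate(x: Tensor, p: int) -> Tensor:
    """Edge-replicate padding of the two spatial axes by ``p`` pixels."""
    n, c, h, w = x.shape
    out_data = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), mode="edge")
    rows = np.clip(np.arange(h + 2 * p) - p, 0, h - 1)
    cols = np.clip(np.arange(w + 2 * p) - p, 0, w - 1)

    def backward(g):
        tmp = np.zeros((n, c, h, w + 2 * p), dtype=g.dtype)
        np.add.at(tmp, (slice(None), slice(None), rows), g)
        dx = np.zeros((n, c, h, w), dtype=g.dtype)
        np.add.at(dx.transpose(0, 1, 3, 2), (slice(None), slice(None), cols),
                  tmp.transpose(0, 1, 3, 2))
        x._accum(dx)

    return _node(out_data, (x,), backward)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    f = int(factor)
    out_data = x.data.repeat(f, axis=2).repeat(f, axis=3)

    def backward(g):
        n, c, h, w = x.shape
        x._accum(g.reshape(n, c, h, f, w, f).sum(axis=(3, 5)))

    return _node(out_data, (x,), backward)


def _bilinear_plan(n_in: int, n_out: int):
    """half-pixel-aligned source indices and weights for 1-D interpolation."""
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(np.int64)
    hi = np.minimum(lo + 1, n_in - 1)
    w_hi = (src - lo).astype(np.float32)
    return lo, hi, 1.0 - w_hi, w_hi


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    n, c, h, w = x.shape
    ho, wo = h * factor, w * factor
    ylo, yhi, wy0, wy1 = _bilinear_plan(h, ho)
    xlo, xhi, wx0, wx1 = _bilinear_plan(w, wo)
    d = x.data
    top = d[:, :, ylo][:, :, :, xlo] * (wy0[:, None] * wx0[None, :]) \
        + d[:, :, ylo][:, :, :, xhi] * (wy0[:, None] * wx1[None, :])
    bot = d[:, :, yhi][:, :, :, xlo] * (wy1[:, None] * wx0[None, :]) \
        + d[:, :, yhi][:, :, :, xhi] * (wy1[:, None] * wx1[None, :])
    out_data = top + bot

    def backward(g):
        dx = np.zeros_like(d)
        yy_lo = np.broadcast_to(ylo[:, None], (ho, wo))
        yy_hi = np.broadcast_to(yhi[:, None], (ho, wo))
        xx_lo = np.broadcast_to(xlo[None, :], (ho, wo))
        xx_hi = np.broadcast_to(xhi[None, :], (ho, wo))
        for yy, xx, ww in (
            (yy_lo, xx_lo, wy0[:, None] * wx0[None, :]),
            (yy_lo, xx_hi, wy0[:, None] * wx1[None, :]),
            (yy_hi, xx_lo, wy1[:, None] * wx0[None, :]),
            (yy_hi, xx_hi, wy1[:, None] * wx1[None, :]),
        ):
            np.add.at(dx, (slice(None), slice(None), yy, xx), g * ww)
        x._accum(dx)

    return _node(out_data, (x,), backward)
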