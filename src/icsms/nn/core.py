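"""Reverse-mode autodiff on numpy arrays.

A deliberately small tape-based engine: only the operations needed by the
mobile-CNN family in this package (elementwise arithmetic, matmul, 2-D
convolution with optional depthwise grouping, max pooling, batch norm,
reductions, reshapes and a fused softmax cross-entropy). Arrays are float32
throughout; gradients are accumulated into ``Tensor.grad``.

MAC accounting for the budget audit is instrumented directly in the conv /
matmul primitives (one multiply-accumulate per weight multiply), switched on
with :func:`count_macs_enabled`.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

_MAC_COUNTER: list[int] | None = None


@contextlib.contextmanager
def count_macs_enabled():
    """Context manager that counts conv/linear multiply-accumulates."""
    global _MAC_COUNTER
    prev = _MAC_COUNTER
    _MAC_COUNTER = [0]
    try:
        yield _MAC_COUNTER
    finally:
        _MAC_COUNTER = prev


def _add_macs(n: int) -> None:
    if _MAC_COUNTER is not None:
        _MAC_COUNTER[0] += int(n)


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- basic protocol -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- graph ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; training graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = _accum(self.grad, np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators ------------------------------------------------------
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

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, pow_(other, -1.0))
        return mul(self, 1.0 / float(other))

    def __neg__(self):
        return mul(self, -1.0)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)


def _accum(g: np.ndarray | None, delta: np.ndarray) -> np.ndarray:
    if g is None:
        return delta.astype(np.float32, copy=True)
    g += delta
    return g


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum grad down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(p for p in parents),
                  backward=backward if req else None)


# -- elementwise ---------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, _unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.grad = _accum(b.grad, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, _unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.grad = _accum(b.grad, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def pow_(a, p: float) -> Tensor:
    a = _wrap(a)
    out_data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), backward)


def clip(a, lo: float | None, hi: float | None) -> Tensor:
    """Clamp; gradient flows only through the un-clamped region."""
    a = _wrap(a)
    out_data = np.clip(a.data, lo, hi)

    def backward(g):
        if a.requires_grad:
            mask = np.ones_like(a.data)
            if lo is not None:
                mask *= a.data > lo
            if hi is not None:
                mask *= a.data < hi
            a.grad = _accum(a.grad, g * mask)

    return _make(out_data, (a,), backward)


def relu(a) -> Tensor:
    return clip(a, 0.0, None)


def relu6(a) -> Tensor:
    return clip(a, 0.0, 6.0)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))

    def backward(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def hard_sigmoid(a) -> Tensor:
    """relu6(x + 3) / 6 — the piecewise-linear sigmoid of mobile nets."""
    return mul(relu6(add(a, 3.0)), 1.0 / 6.0)


def hard_swish(a) -> Tensor:
    """x * hard_sigmoid(x)."""
    return mul(a, hard_sigmoid(a))


# -- shape ops -----------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    out_data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, np.transpose(g, inv))

    return _make(out_data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int) -> Tensor:
    ts = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(int(lo), int(hi))
                t.grad = _accum(t.grad, g[tuple(idx)])

    return _make(out_data, tuple(ts), backward)


def narrow(a, axis: int, start: int, length: int) -> Tensor:
    a = _wrap(a)
    idx = [slice(None)] * a.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    out_data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[idx] = g
            a.grad = _accum(a.grad, full)

    return _make(out_data, (a,), backward)


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            if axis is None:
                grad = np.broadcast_to(g, a.data.shape)
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                grad = np.broadcast_to(gg, a.data.shape)
            a.grad = _accum(a.grad, grad.astype(np.float32))

    return _make(out_data, (a,), backward)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in ax]))
    return mul(sum_(a, axis, keepdims), 1.0 / n)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data
    _add_macs(out_data.size // out_data.shape[-1] * a.data.shape[-1]
              * b.data.shape[-1])

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a.grad = _accum(a.grad, _unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b.grad = _accum(b.grad, _unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


# -- convolution ---------------------------------------------------------

def _pad_nchw(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def conv2d(x, w, b=None, stride: int | tuple[int, int] = 1,
           padding: int | tuple[int, int] = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (Co, Ci/groups, kh, kw).

    Supported grouping: 1 (dense) or Ci (depthwise, one filter per channel).
    """
    x, w = _wrap(x), _wrap(w)
    if b is not None:
        b = _wrap(b)
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    n, ci, h, wd = x.shape
    co, cig, kh, kw = w.shape
    if groups not in (1, ci):
        raise ValueError("conv2d supports groups=1 or depthwise groups=Ci")
    if groups == 1 and cig != ci:
        raise ValueError(f"channel mismatch: input has {ci}, weight expects {cig}")
    if groups == ci and (cig != 1 or co != ci):
        raise ValueError("depthwise conv requires weight (C, 1, kh, kw)")
    xp = _pad_nchw(x.data, ph, pw)
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (wd + 2 * pw - kw) // sw + 1
    _add_macs(n * ho * wo * co * cig * kh * kw)

    if groups == ci:  # depthwise: accumulate over kernel offsets
        out = np.zeros((n, co, ho, wo), dtype=np.float32)
        for ki in range(kh):
            for kj in range(kw):
                sl = xp[:, :, ki:ki + sh * ho:sh, kj:kj + sw * wo:sw]
                out += w.data[:, 0, ki, kj][None, :, None, None] * sl

        def backward(g):
            if w.requires_grad:
                gw = np.zeros_like(w.data)
                for ki in range(kh):
                    for kj in range(kw):
                        sl = xp[:, :, ki:ki + sh * ho:sh, kj:kj + sw * wo:sw]
                        gw[:, 0, ki, kj] = (g * sl).sum(axis=(0, 2, 3))
                w.grad = _accum(w.grad, gw)
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for ki in range(kh):
                    for kj in range(kw):
                        gxp[:, :, ki:ki + sh * ho:sh, kj:kj + sw * wo:sw] += \
                            w.data[:, 0, ki, kj][None, :, None, None] * g
                gx = gxp[:, :, ph:ph + h, pw:pw + wd] if (ph or pw) else gxp
                x.grad = _accum(x.grad, gx)
            if b is not None and b.requires_grad:
                b.grad = _accum(b.grad, g.sum(axis=(0, 2, 3)))

    elif kh == 1 and kw == 1 and sh == 1 and sw == 1 and not (ph or pw):
        # pointwise fast path: pure matmul
        w2 = w.data.reshape(co, ci)
        out = (w2 @ xp.reshape(n, ci, h * wd)).reshape(n, co, h, wd)

        def backward(g):
            g2 = g.reshape(n, co, h * wd)
            if w.requires_grad:
                gw = np.einsum("nop,ncp->oc", g2, xp.reshape(n, ci, h * wd),
                               optimize=True)
                w.grad = _accum(w.grad, gw.reshape(w.data.shape))
            if x.requires_grad:
                gx = (w2.T @ g2).reshape(n, ci, h, wd)
                x.grad = _accum(x.grad, gx)
            if b is not None and b.requires_grad:
                b.grad = _accum(b.grad, g.sum(axis=(0, 2, 3)))

    else:  # dense conv via im2col
        cols = np.empty((n, ci * kh * kw, ho * wo), dtype=np.float32)
        idx = 0
        for c_off in range(ci):
            for ki in range(kh):
                for kj in range(kw):
                    cols[:, idx, :] = xp[:, c_off, ki:ki + sh * ho:sh,
                                         kj:kj + sw * wo:sw].reshape(n, -1)
                    idx += 1
        w2 = w.data.reshape(co, ci * kh * kw)
        out = (w2 @ cols).reshape(n, co, ho, wo)

        def backward(g):
            g2 = g.reshape(n, co, ho * wo)
            if w.requires_grad:
                gw = np.einsum("nop,nkp->ok", g2, cols, optimize=True)
                w.grad = _accum(w.grad, gw.reshape(w.data.shape))
            if x.requires_grad:
                gcols = np.einsum("ok,nop->nkp", w2, g2, optimize=True)
                gxp = np.zeros_like(xp)
                idx2 = 0
                for c_off in range(ci):
                    for ki in range(kh):
                        for kj in range(kw):
                            gxp[:, c_off, ki:ki + sh * ho:sh,
                                kj:kj + sw * wo:sw] += \
                                gcols[:, idx2, :].reshape(n, ho, wo)
                            idx2 += 1
                gx = gxp[:, :, ph:ph + h, pw:pw + wd] if (ph or pw) else gxp
                x.grad = _accum(x.grad, gx)
            if b is not None and b.requires_grad:
                b.grad = _accum(b.grad, g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    if b is not None:
        out = out + b.data[None, :, None, None]
    return _make(out, parents, backward)


def max_pool2d(x, kernel: int, stride: int | None = None,
               padding: int = 0) -> Tensor:
    """Max pooling; on ties the gradient is routed to every maximal cell."""
    x = _wrap(x)
    stride = stride or kernel
    n, c, h, w = x.shape
    xp = x.data
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2),
                    constant_values=-np.inf)
    ho = (h + 2 * padding - kernel) // stride + 1
    wo = (w + 2 * padding - kernel) // stride + 1
    out = np.full((n, c, ho, wo), -np.inf, dtype=np.float32)
    for ki in range(kernel):
        for kj in range(kernel):
            sl = xp[:, :, ki:ki + stride * ho:stride, kj:kj + stride * wo:stride]
            np.maximum(out, sl, out=out)

    def backward(g):
        if not x.requires_grad:
            return
        gxp = np.zeros_like(xp)
        for ki in range(kernel):
            for kj in range(kernel):
                sl = xp[:, :, ki:ki + stride * ho:stride,
                        kj:kj + stride * wo:stride]
                gxp[:, :, ki:ki + stride * ho:stride,
                    kj:kj + stride * wo:stride] += g * (sl == out)
        gx = gxp[:, :, padding:padding + h, padding:padding + w] \
            if padding else gxp
        x.grad = _accum(x.grad, gx)

    return _make(out, (x,), backward)


def avg_pool2d(x, kernel: int) -> Tensor:
    """Non-overlapping average pooling (spatial dims divisible by kernel)."""
    x = _wrap(x)
    n, c, h, w = x.shape
    if h % kernel or w % kernel:
        raise ValueError("avg_pool2d requires divisible spatial dims")
    r = reshape(x, (n, c, h // kernel, kernel, w // kernel, kernel))
    return mean(r, axis=(3, 5))


def batch_norm2d(x, gamma, beta, running_mean, running_var,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Batch norm over (N, H, W) per channel; updates running stats in-place."""
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    n, c, h, w = x.shape
    if training:
        m = x.data.mean(axis=(0, 2, 3))
        v = x.data.var(axis=(0, 2, 3))
        cnt = n * h * w
        running_mean *= (1.0 - momentum)
        running_mean += momentum * m
        running_var *= (1.0 - momentum)
        # unbiased variance for the running estimate, biased for the batch
        running_var += momentum * (v * cnt / max(cnt - 1, 1))
    else:
        m, v = running_mean, running_var
    inv_std = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if beta.requires_grad:
            beta.grad = _accum(beta.grad, g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma.grad = _accum(gamma.grad, (g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = gamma.data[None, :, None, None] * g
            if training:
                cnt = n * h * w
                mean_gs = gs.mean(axis=(0, 2, 3), keepdims=True)
                mean_gs_xhat = (gs * xhat).mean(axis=(0, 2, 3), keepdims=True)
                gx = (gs - mean_gs - xhat * mean_gs_xhat) \
                    * inv_std[None, :, None, None]
            else:
                gx = gs * inv_std[None, :, None, None]
            x.grad = _accum(x.grad, gx.astype(np.float32))

    return _make(out, (x, gamma, beta), backward)


def cross_entropy_with_logits(logits, labels: np.ndarray) -> Tensor:
    """Mean over the batch of -log softmax(logits)[true class], natural log."""
    logits = _wrap(logits)
    labels = np.asarray(labels)
    n, c = logits.shape
    if labels.shape != (n,):
        raise ValueError("labels must be a vector matching the batch size")
    if labels.min() < 0 or labels.max() >= c:
        raise IndexError("label out of range")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    nll = -(z[np.arange(n), labels] - np.log(ez.sum(axis=1)))
    out = np.float32(nll.mean())

    def backward(g):
        if logits.requires_grad:
            gl = p.copy()
            gl[np.arange(n), labels] -= 1.0
            logits.grad = _accum(logits.grad, (g * gl / n).astype(np.float32))

    return _make(out, (logits,), backward)
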