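"""Reverse-mode automatic differentiation over numpy arrays.

A minimal tape-based engine: each :class:`Tensor` wraps a float array and,
when it results from an operation, keeps closures that push its gradient to
its parents.  ``backward()`` runs the closures in reverse topological order.
Only the operations the segmentation network needs are provided; all arrays
are float32 unless the caller supplies float64.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "mul",
    "matmul",
    "reshape",
    "transpose",
    "concat",
    "relu",
    "gelu",
    "sigmoid",
    "softmax",
    "layer_norm",
    "tsum",
    "tmean",
    "tmax",
    "tmax_channel",
    "tmean_channel",
    "conv2d",
    "maxpool2d",
    "interp_bilinear",
    "bce_with_logits",
]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32 if np.asarray(data).dtype != np.float64 else np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self) = 1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Light operator sugar used throughout the model code.
    def __add__(self, other):
        return add(self, as_tensor(other))

    def __radd__(self, other):
        return add(as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    def __rmul__(self, other):
        return mul(as_tensor(other), self)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), as_tensor(-1.0)))

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents: Sequence[Tensor], backward: Callable[[np.ndarray], None]) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(a.data * b.data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with numpy's stacked-matmul broadcasting."""

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        a._accumulate(_unbroadcast(ga, a.data.shape))
        b._accumulate(_unbroadcast(gb, b.data.shape))

    return _node(np.matmul(a.data, b.data), (a, b), backward)


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape

    def backward(g):
        a._accumulate(g.reshape(old))

    return _node(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def backward(g):
        a._accumulate(g.transpose(inv))

    return _node(a.data.transpose(axes), (a,), backward)


def concat(parts: Sequence[Tensor], axis: int = 0) -> Tensor:
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            p._accumulate(g[tuple(idx)])

    return _node(np.concatenate([p.data for p in parts], axis=axis), tuple(parts), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _node(a.data * mask, (a,), backward)


def gelu(a: Tensor) -> Tensor:
    """Gaussian-error linear unit (tanh approximation)."""
    c = np.sqrt(2.0 / np.pi).astype(np.float32)
    x = a.data
    inner = c * (x + 0.044715 * x**3)
    t = np.tanh(inner)
    out = 0.5 * x * (1.0 + t)

    def backward(g):
        dinner = c * (1.0 + 3 * 0.044715 * x**2)
        d = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
        a._accumulate(g * d)

    return _node(out, (a,), backward)


def _expit(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = _expit(a.data)

    def backward(g):
        a._accumulate(g * s * (1.0 - s))

    return _node(s, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        a._accumulate(s * (g - dot))

    return _node(s, (a,), backward)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod([a.data.shape[ax] for ax in np.atleast_1d(axis)])
    s = tsum(a, axis=axis, keepdims=keepdims)
    return mul(s, as_tensor(np.float32(1.0 / n)))


def tmax(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Max over one axis; ties route the gradient to the first maximum."""
    idx = a.data.argmax(axis=axis)
    out_k = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)
    out = out_k if keepdims else np.squeeze(out_k, axis=axis)

    def backward(g):
        gk = g if keepdims else np.expand_dims(g, axis)
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, np.expand_dims(idx, axis), gk, axis=axis)
        a._accumulate(ga)

    return _node(out, (a,), backward)


def tmean_channel(a: Tensor) -> Tensor:
    """Mean over the channel axis of a (C,H,W) map, keeping a 1×H×W result."""
    return tmean(a, axis=0, keepdims=True)


def tmax_channel(a: Tensor) -> Tensor:
    """Max over the channel axis of a (C,H,W) map, 1×H×W; ties route the
    gradient to the first maximal channel."""
    idx = a.data.argmax(axis=0)  # (H, W)
    out = np.take_along_axis(a.data, idx[None], axis=0)

    def backward(g):
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, idx[None], g, axis=0)
        a._accumulate(ga)

    return _node(out, (a,), backward)


def layer_norm(a: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis."""
    mu = a.data.mean(axis=-1, keepdims=True)
    xc = a.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma.data + beta.data

    def backward(g):
        n = a.data.shape[-1]
        gxhat = g * gamma.data
        ga = inv * (gxhat - gxhat.mean(axis=-1, keepdims=True) - xhat * (gxhat * xhat).mean(axis=-1, keepdims=True))
        a._accumulate(ga)
        gamma._accumulate(_unbroadcast(g * xhat, gamma.data.shape))
        beta._accumulate(_unbroadcast(g, beta.data.shape))

    return _node(out, (a, gamma, beta), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding: int) -> Tensor:
    """2-D cross-correlation on a (Cin,H,W) map with (Cout,Cin,kh,kw) kernel.

    Stride 1; output spatial size is preserved when padding = (k-1)/2.
    Implemented by im2col + one GEMM; the backward pass scatters the column
    gradient with a small loop over kernel offsets.
    """
    cin, h, wd = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, kernel {cin_w}")
    xp = np.pad(x.data, ((0, 0), (padding, padding), (padding, padding))) if padding else x.data
    ho = xp.shape[1] - kh + 1
    wo = xp.shape[2] - kw + 1
    # (Cin, ho, wo, kh, kw) view, no copy
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    cols = win.transpose(1, 2, 0, 3, 4).reshape(ho * wo, cin * kh * kw)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out = cols @ wmat.T
    if b is not None:
        out += b.data
    out = out.T.reshape(cout, ho, wo)

    def backward(g):
        g2 = g.reshape(cout, ho * wo).T  # (ho*wo, cout)
        w._accumulate((g2.T @ cols).reshape(w.data.shape))
        if b is not None:
            b._accumulate(g2.sum(axis=0))
        gcols = (g2 @ wmat).reshape(ho, wo, cin, kh, kw)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, i : i + ho, j : j + wo] += gcols[:, :, :, i, j].transpose(2, 0, 1)
        if padding:
            gxp = gxp[:, padding:-padding, padding:-padding]
        x._accumulate(gxp)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def maxpool2d(x: Tensor) -> Tensor:
    """2×2 max pooling, stride 2, on a (C,H,W) map with even H, W."""
    c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2d needs even spatial size, got {h}x{w}")
    xr = x.data.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros((c, h // 2, w // 2, 4), dtype=x.data.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = gr.reshape(c, h // 2, w // 2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h, w)
        x._accumulate(gx)

    return _node(out, (x,), backward)


def _interp_matrix(n_out: int, n_in: int, dtype=np.float32) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (align_corners=False)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        t = src - lo
        m[i, lo] += 1.0 - t
        m[i, hi] += t
    return m


def interp_bilinear(x: Tensor, h_out: int, w_out: int) -> Tensor:
    """Bilinear resize of a (C,H,W) map to (C,h_out,w_out)."""
    c, h, w = x.data.shape
    a = _interp_matrix(h_out, h, x.data.dtype)
    bm = _interp_matrix(w_out, w, x.data.dtype)
    out = np.einsum("oh,chw,pw->cop", a, x.data, bm, optimize=True)

    def backward(g):
        x._accumulate(np.einsum("oh,cop,pw->chw", a, g, bm, optimize=True))

    return _node(out, (x,), backward)


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Pixel-mean binary cross-entropy on raw logits (numerically stable)."""
    z = logits.data
    t = np.asarray(target, dtype=z.dtype)
    # log(1+e^z) computed stably
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def backward(g):
        logits._accumulate(g * (_expit(z) - t) / n)

    return _node(loss.mean(), (logits,), backward)
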