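"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Provides exactly the operator set the volumetric segmentation network
needs: broadcasting arithmetic, ReLU/sigmoid/exp/log, axis reductions,
channel-last 3-D convolution (via im2col), non-overlapping 2x transpose
convolution, 3x3x3/stride-2 max pooling, concatenation and an Adam
optimizer.  Tensors are channel-last: (batch, H, W, D, C).

Float32 is used throughout for speed; gradients are accumulated in the
same dtype.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    """A NumPy array plus gradient bookkeeping for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=DTYPE).copy()
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar or any-shape) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- operator sugar ------------------------------------------------------
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
        return mul(self, pow_(other, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return pow_(self, p)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# Elementwise and broadcasting primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _make(a.data + b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), backward)


def pow_(a, p: float) -> Tensor:
    a = as_tensor(a)
    p = float(p)
    out_data = a.data ** p

    def backward(g):
        a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(np.log(a.data), (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes through only inside [lo, hi]."""
    a = as_tensor(a)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        a._accumulate(g * mask)

    return _make(np.clip(a.data, lo, hi), (a,), backward)


# ---------------------------------------------------------------------------
# Reductions and shape ops
# ---------------------------------------------------------------------------

def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape))

    return _make(out_data, (a,), backward)


def mean_(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(sum_(a, axis, keepdims), 1.0 / float(n))


def max_(a, axis: int, keepdims=False) -> Tensor:
    """Max over a single axis; ties route the gradient to the first argmax."""
    a = as_tensor(a)
    idx = np.argmax(a.data, axis=axis)
    out_data = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)
    if not keepdims:
        out_data = np.squeeze(out_data, axis=axis)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, np.expand_dims(idx, axis), g, axis=axis)
        a._accumulate(ga)

    return _make(out_data, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.shape

    def backward(g):
        a._accumulate(g.reshape(old))

    return _make(a.data.reshape(shape), (a,), backward)


def concat(tensors, axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


def softmax(a, axis: int) -> Tensor:
    """Numerically stable softmax along ``axis`` (composite op)."""
    a = as_tensor(a)
    shift = Tensor(np.max(a.data, axis=axis, keepdims=True))  # constant
    e = exp(a - shift)
    return e / sum_(e, axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# 3-D convolution family (channel-last: b, H, W, D, C)
# ---------------------------------------------------------------------------

def conv3d(x, w, b=None) -> Tensor:
    """Same-padded, stride-1 3-D convolution.

    x: (batch, H, W, D, C_in); w: (k, k, k, C_in, C_out); b: (C_out,).
    The kernel is applied in cross-correlation orientation, the
    convention of every deep-learning framework.
    """
    x, w = as_tensor(x), as_tensor(w)
    k = w.shape[0]
    if k % 2 != 1:
        raise ValueError(f"kernel size must be odd, got {k}")
    pad = k // 2
    bs, H, W, D, Cin = x.shape
    Cout = w.shape[4]
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (pad, pad), (0, 0)))
    # windows: (b, H, W, D, C, k, k, k) -> columns (b*H*W*D, k^3*C)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    col = np.ascontiguousarray(np.moveaxis(win, 4, 7)).reshape(-1, k * k * k * Cin)
    wmat = w.data.reshape(k * k * k * Cin, Cout)
    out_data = (col @ wmat).reshape(bs, H, W, D, Cout)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data
        parents.append(b)

    def backward(g):
        gflat = g.reshape(-1, Cout)
        w._accumulate((col.T @ gflat).reshape(w.shape))
        if b is not None:
            b._accumulate(gflat.sum(axis=0))
        gcol = (gflat @ wmat.T).reshape(bs, H, W, D, k, k, k, Cin)
        gxp = np.zeros_like(xp)
        for a_ in range(k):
            for b_ in range(k):
                for c_ in range(k):
                    gxp[:, a_:a_ + H, b_:b_ + W, c_:c_ + D, :] += gcol[:, :, :, :, a_, b_, c_, :]
        x._accumulate(gxp[:, pad:pad + H, pad:pad + W, pad:pad + D, :])

    return _make(out_data, tuple(parents), backward)


def conv_transpose3d_2x(x, w, b=None) -> Tensor:
    """Kernel-2 / stride-2 transpose convolution (exact 2x upsampling).

    x: (batch, h, w, d, C_in); w: (2, 2, 2, C_in, C_out).  Kernel equals
    stride, so output blocks do not overlap.
    """
    x, w = as_tensor(x), as_tensor(w)
    bs, h, ww, d, Cin = x.shape
    Cout = w.shape[4]
    t = np.einsum("bijkc,pqrco->bipjqkro", x.data, w.data)
    out_data = t.reshape(bs, 2 * h, 2 * ww, 2 * d, Cout)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data
        parents.append(b)

    def backward(g):
        gt = g.reshape(bs, h, 2, ww, 2, d, 2, Cout)
        x._accumulate(np.einsum("bipjqkro,pqrco->bijkc", gt, w.data))
        w._accumulate(np.einsum("bijkc,bipjqkro->pqrco", x.data, gt))
        if b is not None:
            b._accumulate(g.reshape(-1, Cout).sum(axis=0))

    return _make(out_data, tuple(parents), backward)


def maxpool3d(x) -> Tensor:
    """3x3x3 max pooling, stride 2, pad 1: halves even spatial dims."""
    x = as_tensor(x)
    bs, H, W, D, C = x.shape
    if H % 2 or W % 2 or D % 2:
        raise ValueError("maxpool3d requires even spatial dimensions")
    neg = np.finfo(DTYPE).min
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)),
                constant_values=neg)
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))
    win = win[:, ::2, ::2, ::2]            # (b, H/2, W/2, D/2, C, 3, 3, 3)
    Ho, Wo, Do = win.shape[1:4]
    flat = win.reshape(*win.shape[:5], 27)
    idx = np.argmax(flat, axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gw = np.zeros(flat.shape, dtype=DTYPE)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gw = gw.reshape(win.shape)
        gxp = np.zeros_like(xp)
        for a_ in range(3):
            for b_ in range(3):
                for c_ in range(3):
                    gxp[:, a_:a_ + 2 * Ho:2, b_:b_ + 2 * Wo:2, c_:c_ + 2 * Do:2, :] += \
                        gw[..., a_, b_, c_]
        x._accumulate(gxp[:, 1:1 + H, 1:1 + W, 1:1 + D, :])

    return _make(out_data, (x,), backward)


def global_avg_pool(x) -> Tensor:
    """Mean over the three spatial axes, keeping dims: (b,1,1,1,C)."""
    return mean_(x, axis=(1, 2, 3), keepdims=True)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
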