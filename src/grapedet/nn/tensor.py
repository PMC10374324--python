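"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` accumulates gradients by reverse topological
traversal.  The op set is exactly what a one-stage convolutional detector
needs: broadcast arithmetic, matmul, the activations (sigmoid, tanh, softplus,
leaky ReLU, arctan), reductions, concat/reshape/slice, 2-D convolution via
im2col, same-padded max pooling and nearest-neighbour upsampling.

The functional helpers (``log``, ``exp``, ``minimum`` ...) dispatch on type so
numerical code (e.g. the loss formulas) can be written once and evaluated on
either plain arrays or differentiable tensors.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "exp", "log", "tanh", "sigmoid", "softplus", "arctan",
    "relu", "leaky_relu", "mish",
    "minimum", "maximum", "clip", "where",
    "concat", "conv2d", "maxpool2d_3x3", "maxpool_same", "upsample2x", "avgpool_all",
]


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode).

    Inside the context no op records parents or backward closures, so large
    intermediate buffers (e.g. im2col workspaces) are freed as soon as the
    forward pass moves on.
    """

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make ndarray <op> Tensor defer to the reflected Tensor operators instead
    # of numpy broadcasting over the Tensor as an opaque object
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        if not _GRAD_ENABLED:
            _parents, _backward = (), None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    __float__ = item

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        # reverse topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def _bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        _attach(out, _bwd)
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        _attach(out, lambda g: self._accum(-g))
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def _bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        _attach(out, _bwd)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def _bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        _attach(out, _bwd)
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data**p, _parents=(self,))

        def _bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        _attach(out, _bwd)
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def _bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        _attach(out, _bwd)
        return out

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.shape
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        _attach(out, lambda g: self._accum(g.reshape(src)))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        _attach(out, lambda g: self._accum(g.transpose(inv)))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def _bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        _attach(out, _bwd)
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def _bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                ax = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                self._accum(np.broadcast_to(g, self.shape).copy())

        _attach(out, _bwd)
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _attach(out: Tensor, bwd) -> None:
    """Attach a backward closure only when the output participates in a
    gradient computation; otherwise let its buffers be collected."""
    if out.requires_grad:
        out._backward = bwd


def _unbroadcast(g, shape):
    """Reduce a broadcast gradient back to ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- elementwise functions (dispatch on type) ------------------------------

def _unary(x, fwd, dfn):
    if not isinstance(x, Tensor):
        return fwd(np.asarray(x))
    y = fwd(x.data)
    out = Tensor(y, _parents=(x,))

    def _bwd(g):
        if x.requires_grad:
            x._accum(g * dfn(x.data, y))

    _attach(out, _bwd)
    return out


def exp(x):
    return _unary(x, np.exp, lambda t, y: y)


def log(x):
    return _unary(x, np.log, lambda t, y: 1.0 / t)


def tanh(x):
    return _unary(x, np.tanh, lambda t, y: 1.0 - y**2)


def sigmoid(x):
    def fwd(t):
        out = np.empty_like(t, dtype=np.result_type(t, np.float32))
        pos = t >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
        e = np.exp(t[~pos])
        out[~pos] = e / (1.0 + e)
        return out

    return _unary(x, fwd, lambda t, y: y * (1.0 - y))


def softplus(x):
    """Numerically stable ``ln(1 + e^x)``."""

    def fwd(t):
        return np.where(t > 30, t, np.log1p(np.exp(np.minimum(t, 30))))

    def dfn(t, y):
        s = np.empty_like(y)
        pos = t >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
        e = np.exp(t[~pos])
        s[~pos] = e / (1.0 + e)
        return s

    return _unary(x, fwd, dfn)


def arctan(x):
    return _unary(x, np.arctan, lambda t, y: 1.0 / (1.0 + t**2))


def relu(x):
    return _unary(x, lambda t: np.maximum(t, 0), lambda t, y: (t > 0).astype(t.dtype))


def leaky_relu(x, slope: float = 0.1):
    return _unary(
        x,
        lambda t: np.where(t > 0, t, slope * t),
        lambda t, y: np.where(t > 0, 1.0, slope).astype(t.dtype),
    )


def mish(x):
    """Self-gated smooth activation ``x * tanh(softplus(x))``."""
    return x * tanh(softplus(x))


def minimum(a, b):
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.minimum(a, b)
    a, b = as_tensor(a), as_tensor(b)
    mask = a.data <= b.data
    out = Tensor(np.where(mask, a.data, b.data), _parents=(a, b))

    def _bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~mask, b.shape))

    _attach(out, _bwd)
    return out


def maximum(a, b):
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.maximum(a, b)
    a, b = as_tensor(a), as_tensor(b)
    mask = a.data >= b.data
    out = Tensor(np.where(mask, a.data, b.data), _parents=(a, b))

    def _bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~mask, b.shape))

    _attach(out, _bwd)
    return out


def clip(x, lo, hi):
    """Clamp; gradient is zero outside ``[lo, hi]``."""
    if not isinstance(x, Tensor):
        return np.clip(x, lo, hi)
    inside = (x.data >= lo) & (x.data <= hi)
    out = Tensor(np.clip(x.data, lo, hi), _parents=(x,))

    def _bwd(g):
        if x.requires_grad:
            x._accum(g * inside)

    _attach(out, _bwd)
    return out


def where(cond, a, b):
    cond = np.asarray(cond)
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return np.where(cond, a, b)
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(np.where(cond, a.data, b.data), _parents=(a, b))

    def _bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * cond, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~cond, b.shape))

    _attach(out, _bwd)
    return out


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    _attach(out, _bwd)
    return out


# -- spatial ops (NCHW) ----------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (x.shape[2] - kh) // stride + 1
    ow = (x.shape[3] - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]          # n, c, oh, ow, kh, kw
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
    return np.ascontiguousarray(col), oh, ow


def _col2im(dcol, x_shape, kh, kw, stride, pad):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    dcol = dcol.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    dx = np.zeros((n, c, hp, wp), dtype=dcol.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += dcol[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight ``(OC, C, KH, KW)``."""
    oc, c, kh, kw = weight.shape
    n = x.shape[0]
    col, oh, ow = _im2col(x.data, kh, kw, stride, padding)
    wmat = weight.data.reshape(oc, -1).T
    out_data = col @ wmat
    if bias is not None:
        out_data = out_data + bias.data
    out_data = out_data.reshape(n, oh, ow, oc).transpose(0, 3, 1, 2)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(np.ascontiguousarray(out_data), _parents=parents)

    def _bwd(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, oc)
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=0))
        if weight.requires_grad:
            weight._accum((col.T @ gmat).T.reshape(weight.shape))
        if x.requires_grad:
            dcol = gmat @ wmat.T
            x._accum(_col2im(dcol, x.shape, kh, kw, stride, padding))

    _attach(out, _bwd)
    return out


def maxpool2d_3x3(x: Tensor) -> Tensor:
    """3x3, stride-1, same-padded max pool (pad value -inf)."""
    n, c, h, w = x.shape
    neg = np.finfo(x.data.dtype).min if np.issubdtype(x.data.dtype, np.floating) else -np.inf
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)), constant_values=neg)
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    out_data = win.max(axis=(4, 5))
    out = Tensor(np.ascontiguousarray(out_data), _parents=(x,))

    def _bwd(g):
        if not x.requires_grad:
            return
        dxp = np.zeros_like(xp)
        remaining = np.ones_like(out_data, dtype=bool)
        for i in range(3):
            for j in range(3):
                hit = remaining & (xp[:, :, i:i + h, j:j + w] == out_data)
                dxp[:, :, i:i + h, j:j + w] += np.where(hit, g, 0)
                remaining &= ~hit
        x._accum(dxp[:, :, 1:-1, 1:-1])

    _attach(out, _bwd)
    return out


def maxpool_same(x: Tensor, kernel: int) -> Tensor:
    """Odd-kernel, stride-1, same-padded max pool.

    Composed from 3x3 pools: with -inf padding, k same-padded 3x3 dilations
    equal one (2k+1)-kernel dilation, so kernels 5/9/13 cost k = 2/4/6 cheap
    passes instead of one huge im2col.
    """
    if kernel % 2 != 1 or kernel < 3:
        raise ValueError("kernel must be odd and >= 3")
    reps = (kernel - 1) // 2
    for _ in range(reps):
        x = maxpool2d_3x3(x)
    return x


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    n, c, h, w = x.shape
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), _parents=(x,))

    def _bwd(g):
        if x.requires_grad:
            x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    _attach(out, _bwd)
    return out


def avgpool_all(x: Tensor) -> Tensor:
    """Global average over the spatial axes (keepdims)."""
    return x.mean(axis=(2, 3), keepdims=True)
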