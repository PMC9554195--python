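"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small define-by-run engine: each operation returns a new
:class:`Tensor` holding the forward value and a closure that accumulates
gradients into its parents.  Only the operations needed by the encoder–decoder
denoiser, the dense-block classifier and Grad-CAM are provided: dilated and
transposed convolution, pooling, channel gating, linear maps, the two losses,
and elementwise nonlinearities.  Everything runs in float32 on the CPU.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "avg_pool2d",
    "max_pool2d",
    "global_avg_pool",
    "channel_scale",
    "linear",
    "relu",
    "sigmoid",
    "mse_loss",
    "softmax_cross_entropy",
    "softmax",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from a scalar node through the whole graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"

    # -- elementwise arithmetic --------------------------------------------
    def __add__(self, other):
        return _ewise(self, other, np.add, _add_back)

    __radd__ = __add__

    def __sub__(self, other):
        return _ewise(self, other, np.subtract, _sub_back)

    def __mul__(self, other):
        return _ewise(self, other, np.multiply, _mul_back)

    __rmul__ = __mul__

    def __neg__(self):
        out = _make(np.negative(self.data), (self,))
        if out._backward is not None:

            def back(g, a=self):
                a._accumulate(-g)

            out._backward = back
        return out

    def reshape(self, *shape):
        orig = self.data.shape
        out = _make(self.data.reshape(*shape), (self,))
        if out._backward is not None:

            def back(g, a=self, orig=orig):
                a._accumulate(g.reshape(orig))

            out._backward = back
        return out

    def pick(self, *index) -> "Tensor":
        """Select one scalar entry, keeping it in the graph."""
        val = np.asarray(self.data[index], dtype=np.float32).reshape(())
        out = _make(val, (self,))
        if out._backward is not None:

            def back(g, a=self, index=index):
                full = np.zeros_like(a.data)
                full[index] = g
                a._accumulate(full)

            out._backward = back
        return out

    def sum(self) -> "Tensor":
        out = _make(np.float32(self.data.sum()), (self,))
        if out._backward is not None:

            def back(g, a=self):
                a._accumulate(np.full_like(a.data, np.float32(g)))

            out._backward = back
        return out

    def mean(self) -> "Tensor":
        n = self.data.size
        out = _make(np.float32(self.data.mean()), (self,))
        if out._backward is not None:

            def back(g, a=self, n=n):
                a._accumulate(np.full_like(a.data, np.float32(g / n)))

            out._backward = back
        return out


def _wants_graph(*ts) -> bool:
    return _GRAD_ENABLED and any(isinstance(t, Tensor) for t in ts)


def _make(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED:
        tensor_parents = tuple(p for p in parents if isinstance(p, Tensor))
        out._parents = tensor_parents
        out._backward = lambda g: None  # placeholder, replaced by the op
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `g` down to `shape` (inverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _ewise(a, b, fwd, make_back):
    a_t = a if isinstance(a, Tensor) else None
    b_t = b if isinstance(b, Tensor) else None
    av = a.data if a_t is not None else _as_f32(a)
    bv = b.data if b_t is not None else _as_f32(b)
    out = _make(fwd(av, bv), (a_t, b_t))
    if out._backward is not None:
        out._backward = make_back(a_t, b_t, av, bv)
    return out


def _add_back(a_t, b_t, av, bv):
    def back(g):
        if a_t is not None:
            a_t._accumulate(_unbroadcast(g, av.shape))
        if b_t is not None:
            b_t._accumulate(_unbroadcast(g, bv.shape))

    return back


def _sub_back(a_t, b_t, av, bv):
    def back(g):
        if a_t is not None:
            a_t._accumulate(_unbroadcast(g, av.shape))
        if b_t is not None:
            b_t._accumulate(_unbroadcast(-g, bv.shape))

    return back


def _mul_back(a_t, b_t, av, bv):
    def back(g):
        if a_t is not None:
            a_t._accumulate(_unbroadcast(g * bv, av.shape))
        if b_t is not None:
            b_t._accumulate(_unbroadcast(g * av, bv.shape))

    return back


# -- nonlinearities ---------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = _make(np.maximum(x.data, 0.0), (x,))
    if out._backward is not None:
        mask = x.data > 0

        def back(g, x=x, mask=mask):
            x._accumulate(g * mask)

        out._backward = back
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0), dtype=np.float32))
    out = _make(y, (x,))
    if out._backward is not None:

        def back(g, x=x, y=y):
            x._accumulate(g * y * (1.0 - y))

        out._backward = back
    return out


def concat(tensors: list, axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = _make(data, tuple(tensors))
    if out._backward is not None:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def back(g, tensors=tensors, splits=splits, axis=axis):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                t._accumulate(piece)

        out._backward = back
    return out


# -- convolution primitives -------------------------------------------------

def _conv_out(n: int, k: int, stride: int, pad: int, dil: int) -> int:
    return (n + 2 * pad - dil * (k - 1) - 1) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int, dil: int):
    n, c, h, w = x.shape
    ho = _conv_out(h, kh, stride, pad, dil)
    wo = _conv_out(w, kw, stride, pad, dil)
    if ho <= 0 or wo <= 0:
        raise ValueError(
            f"input {h}x{w} too small for kernel {kh}x{kw} with dilation {dil}"
        )
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        hi = i * dil
        for j in range(kw):
            wi = j * dil
            cols[:, :, i, j] = xp[:, :, hi : hi + stride * ho : stride, wi : wi + stride * wo : stride]
    return cols, ho, wo


def _col2im(cols: np.ndarray, x_shape: tuple, stride: int, pad: int, dil: int) -> np.ndarray:
    n, c, h, w = x_shape
    kh, kw, ho, wo = cols.shape[2], cols.shape[3], cols.shape[4], cols.shape[5]
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        hi = i * dil
        for j in range(kw):
            wi = j * dil
            xp[:, :, hi : hi + stride * ho : stride, wi : wi + stride * wo : stride] += cols[:, :, i, j]
    return xp[:, :, pad : pad + h, pad : pad + w] if pad else xp


def _conv_fwd(x: np.ndarray, w: np.ndarray, stride: int, pad: int, dil: int):
    cout, cin, kh, kw = w.shape
    cols, ho, wo = _im2col(x, kh, kw, stride, pad, dil)
    n = x.shape[0]
    colm = cols.reshape(n, cin * kh * kw, ho * wo)
    out = np.matmul(w.reshape(cout, -1), colm).reshape(n, cout, ho, wo)
    return out, colm


def _conv_bwd_input(dy: np.ndarray, w: np.ndarray, x_shape: tuple, stride: int, pad: int, dil: int) -> np.ndarray:
    cout, cin, kh, kw = w.shape
    n, _, ho, wo = dy.shape
    dcol = np.matmul(w.reshape(cout, -1).T, dy.reshape(n, cout, -1))
    return _col2im(dcol.reshape(n, cin, kh, kw, ho, wo), x_shape, stride, pad, dil)


def _conv_bwd_weight(dy: np.ndarray, colm: np.ndarray, w_shape: tuple) -> np.ndarray:
    cout = w_shape[0]
    n = dy.shape[0]
    dy2 = dy.reshape(n, cout, -1)
    dw = np.matmul(dy2, colm.transpose(0, 2, 1)).sum(axis=0)
    return dw.reshape(w_shape)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D convolution, NCHW layout, weight (C_out, C_in, kH, kW)."""
    y, colm = _conv_fwd(x.data, w.data, stride, padding, dilation)
    if b is not None:
        y += b.data[None, :, None, None]
    out = _make(y, (x, w, b))
    if out._backward is not None:
        x_shape = x.data.shape

        def back(g, x=x, w=w, b=b, colm=colm, x_shape=x_shape):
            x._accumulate(_conv_bwd_input(g, w.data, x_shape, stride, padding, dilation))
            w._accumulate(_conv_bwd_weight(g, colm, w.data.shape))
            if b is not None:
                b._accumulate(g.sum(axis=(0, 2, 3)))

        out._backward = back
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 2) -> Tensor:
    """Transposed convolution (stride = upsampling factor).

    Weight layout (C_in, C_out, kH, kW); output spatial size = input * stride
    for kernel == stride (the only configuration used here: learnable 2x
    upsampling in the decoder).
    """
    cin, cout, kh, kw = w.shape
    n, _, h, wdt = x.data.shape
    out_shape = (n, cout, (h - 1) * stride + kh, (wdt - 1) * stride + kw)
    y = _conv_bwd_input(x.data, w.data, out_shape, stride, 0, 1)
    if b is not None:
        y += b.data[None, :, None, None]
    out = _make(y, (x, w, b))
    if out._backward is not None:

        def back(g, x=x, w=w, b=b):
            dx, colm = _conv_fwd(g, w.data, stride, 0, 1)
            x._accumulate(dx)
            w._accumulate(_conv_bwd_weight(x.data, colm, w.data.shape))
            if b is not None:
                b._accumulate(g.sum(axis=(0, 2, 3)))

        out._backward = back
    return out


# -- pooling ----------------------------------------------------------------

def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial size {h}x{w} not divisible by pool size {k}")
    y = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))
    out = _make(y, (x,))
    if out._backward is not None:

        def back(g, x=x, n=n, c=c, h=h, w=w, k=k):
            gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            x._accumulate(gx.astype(np.float32))

        out._backward = back
    return out


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial size {h}x{w} not divisible by pool size {k}")
    blocks = x.data.reshape(n, c, h // k, k, w // k, k).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(n, c, h // k, w // k, k * k)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = _make(y, (x,))
    if out._backward is not None:

        def back(g, x=x, idx=idx, n=n, c=c, h=h, w=w, k=k):
            gflat = np.zeros((n, c, h // k, w // k, k * k), dtype=np.float32)
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            gx = gflat.reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(gx.reshape(n, c, h, w))

        out._backward = back
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    n, c, h, w = x.data.shape
    y = x.data.mean(axis=(2, 3))
    out = _make(y, (x,))
    if out._backward is not None:

        def back(g, x=x, h=h, w=w):
            x._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape).astype(np.float32))

        out._backward = back
    return out


def channel_scale(x: Tensor, s: Tensor) -> Tensor:
    """Scale each channel of (N, C, H, W) by gates s of shape (N, C)."""
    y = x.data * s.data[:, :, None, None]
    out = _make(y, (x, s))
    if out._backward is not None:

        def back(g, x=x, s=s):
            x._accumulate(g * s.data[:, :, None, None])
            s._accumulate((g * x.data).sum(axis=(2, 3)))

        out._backward = back
    return out


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x (N, C_in) @ w (C_out, C_in)^T + b."""
    y = x.data @ w.data.T
    if b is not None:
        y += b.data
    out = _make(y, (x, w, b))
    if out._backward is not None:

        def back(g, x=x, w=w, b=b):
            x._accumulate(g @ w.data)
            w._accumulate(g.T @ x.data)
            if b is not None:
                b._accumulate(g.sum(axis=0))

        out._backward = back
    return out


# -- losses -----------------------------------------------------------------

def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    t = _as_f32(target)
    diff = pred.data - t
    out = _make(np.float32(np.mean(diff * diff)), (pred,))
    if out._backward is not None:

        def back(g, pred=pred, diff=diff):
            pred._accumulate((2.0 / diff.size) * np.float32(g) * diff)

        out._backward = back
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under softmax(logits)."""
    labels = np.asarray(labels)
    n = logits.data.shape[0]
    p = softmax(logits.data)
    ll = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None))
    out = _make(np.float32(ll.mean()), (logits,))
    if out._backward is not None:

        def back(g, logits=logits, p=p, labels=labels, n=n):
            grad = p.copy()
            grad[np.arange(n), labels] -= 1.0
            logits._accumulate(np.float32(g) * grad / n)

        out._backward = back
    return out
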