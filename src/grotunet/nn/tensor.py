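"""Reverse-mode automatic differentiation over numpy arrays.

A compact tape-based autodiff engine providing exactly the operations the
segmentation network and its discriminative loss need: dense/conv linear
algebra, pooling, normalization primitives, neighborhood unfold/fold for
outlook attention, and bilinear upsampling with a fixed half-pixel-center
convention.  All arithmetic is float32; gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` via topological traversal.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "select",
    "conv2d",
    "maxpool2x2",
    "unfold",
    "fold",
    "upsample_bilinear",
    "softmax",
    "relu",
    "no_grad",
]

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


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        # float32 throughout, except that float64 input is preserved so
        # pure computations (e.g. loss oracles) can run at full precision
        data = np.asarray(data)
        if data.dtype != np.float64:
            data = data.astype(np.float32)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
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
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without argument requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free the tape
        for node in topo:
            node._backward = None
            node._parents = ()

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad and self._backward is None:
            return
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad.astype(self.data.dtype, copy=False)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out._parents:
            def bw(g, a=self, b=other, out=out):
                a._accum(_unbroadcast(g, a.data.shape))
                b._accum(_unbroadcast(g, b.data.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out._parents:
            out._backward = lambda g, a=self: a._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out._parents:
            def bw(g, a=self, b=other):
                a._accum(_unbroadcast(g * b.data, a.data.shape))
                b._accum(_unbroadcast(g * a.data, b.data.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = _make(self.data ** p, (self,))
        if out._parents:
            def bw(g, a=self, p=p):
                a._accum(g * p * a.data ** (p - 1.0))
            out._backward = bw
        return out

    def sqrt(self):
        out = _make(np.sqrt(self.data), (self,))
        if out._parents:
            def bw(g, a=self, o=out):
                a._accum(g * 0.5 / np.maximum(o.data, 1e-12))
            out._backward = bw
        return out

    def abs(self):
        out = _make(np.abs(self.data), (self,))
        if out._parents:
            out._backward = lambda g, a=self: a._accum(g * np.sign(a.data))
        return out

    def exp(self):
        out = _make(np.exp(self.data), (self,))
        if out._parents:
            out._backward = lambda g, a=self, o=out: a._accum(g * o.data)
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _make(self.data @ other.data, (self, other))
        if out._parents:
            def bw(g, a=self, b=other):
                ga = g @ np.swapaxes(b.data, -1, -2)
                gb = np.swapaxes(a.data, -1, -2) @ g
                a._accum(_unbroadcast(ga, a.data.shape))
                b._accum(_unbroadcast(gb, b.data.shape))
            out._backward = bw
        return out

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            def bw(g, a=self, axis=axis, keepdims=keepdims):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.data.shape).astype(np.float32))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out._parents:
            out._backward = lambda g, a=self: a._accum(g.reshape(a.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = _make(np.ascontiguousarray(self.data.transpose(axes)), (self,))
        if out._parents:
            out._backward = lambda g, a=self, inv=tuple(inv): a._accum(g.transpose(inv))
        return out


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    if _grad_enabled:
        track = tuple(p for p in parents if p.requires_grad or p._parents)
        if track:
            out._parents = tuple(parents)
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def select(x: Tensor, index: int) -> Tensor:
    """Index along the first axis, keeping the graph (out = x[index])."""
    out = _make(x.data[index], (x,))
    if out._parents:
        def bw(g, x=x, index=index):
            dx = np.zeros_like(x.data)
            dx[index] = g
            x._accum(dx)
        out._backward = bw
    return out


def relu(x: Tensor) -> Tensor:
    out = _make(np.maximum(x.data, 0.0), (x,))
    if out._parents:
        out._backward = lambda g, a=x: a._accum(g * (a.data > 0))
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = _make(s, (x,))
    if out._parents:
        def bw(g, a=x, s=s, axis=axis):
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accum(s * (g - dot))
        out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bw(g, ts=tuple(tensors), offsets=offsets, axis=axis):
            for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])
        out._backward = bw
    return out


# -- image operations (NCHW) -------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """View padded input as [N, C, kh, kw, Ho, Wo] patch array (no copy)."""
    n, c, h, w = xp.shape
    ho = (h - kh) // sh + 1
    wo = (w - kw) // sw + 1
    sn, sc, sH, sW = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, kh, kw, ho, wo),
        strides=(sn, sc, sH, sW, sH * sh, sW * sw),
        writeable=False,
    )


def conv2d(x: Tensor, w: Tensor, bias: Tensor | None, stride=(1, 1), padding=(0, 0)) -> Tensor:
    """2-D cross-correlation, x: [N,C,H,W], w: [O,C,kh,kw]."""
    sh, sw = stride
    ph, pw = padding
    o, c, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    cols6 = _im2col(xp, kh, kw, sh, sw)
    n, _, _, _, ho, wo = cols6.shape
    cols = np.ascontiguousarray(cols6).reshape(n, c * kh * kw, ho * wo)
    wmat = w.data.reshape(o, c * kh * kw)
    y = (wmat @ cols).reshape(n, o, ho, wo)
    if bias is not None:
        y += bias.data.reshape(1, o, 1, 1)
    parents = (x, w) if bias is None else (x, w, bias)
    out = _make(y, parents)
    if out._parents:
        hp, wp = xp.shape[2], xp.shape[3]

        def bw(g, x=x, w=w, bias=bias, cols=cols, wmat=wmat):
            gm = g.reshape(n, o, ho * wo)
            w._accum(np.matmul(gm, cols.swapaxes(1, 2)).sum(axis=0).reshape(w.data.shape))
            if bias is not None:
                bias._accum(gm.sum(axis=(0, 2)))
            if x.requires_grad or x._parents:
                dcols = np.matmul(wmat.T[None], gm)
                dcols = dcols.reshape(n, c, kh, kw, ho, wo)
                dxp = np.zeros((n, c, hp, wp), dtype=np.float32)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += dcols[:, :, i, j]
                if ph or pw:
                    dxp = dxp[:, :, ph : hp - ph, pw : wp - pw]
                x._accum(dxp)
        out._backward = bw
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 requires even spatial dims, got {h}x{w}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    out = _make(y, (x,))
    if out._parents:
        def bw(g, x=x, idx=idx):
            dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
            np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
            dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accum(dx.reshape(n, c, h, w))
        out._backward = bw
    return out


def unfold(x: Tensor, k: int) -> Tensor:
    """Extract k x k neighborhoods (stride 1, zero pad k//2): -> [N,C,k*k,H*W]."""
    n, c, h, w = x.data.shape
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = np.ascontiguousarray(_im2col(xp, k, k, 1, 1)).reshape(n, c, k * k, h * w)
    out = _make(cols, (x,))
    if out._parents:
        def bw(g, x=x):
            gw = g.reshape(n, c, k, k, h, w)
            dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i : i + h, j : j + w] += gw[:, :, i, j]
            x._accum(dxp[:, :, p : p + h, p : p + w])
        out._backward = bw
    return out


def fold(x: Tensor, k: int, hw: tuple[int, int]) -> Tensor:
    """Adjoint of :func:`unfold`: scatter-add k x k windows back to [N,C,H,W]."""
    h, w = hw
    n, c, kk, _ = x.data.shape
    p = k // 2
    xw = x.data.reshape(n, c, k, k, h, w)
    yp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            yp[:, :, i : i + h, j : j + w] += xw[:, :, i, j]
    y = yp[:, :, p : p + h, p : p + w]
    out = _make(y, (x,))
    if out._parents:
        def bw(g, x=x):
            gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p)))
            cols = np.ascontiguousarray(_im2col(gp, k, k, 1, 1))
            x._accum(cols.reshape(n, c, k * k, h * w))
        out._backward = bw
    return out


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, eps: float) -> Tensor:
    """Fused training-mode batch normalization over (N, H, W) per channel.

    Returns ``(out, batch_mean, batch_var)``; updating running statistics is
    the caller's concern.
    """
    n, c, h, w = x.data.shape
    m = n * h * w
    mu = x.data.mean(axis=(0, 2, 3))
    xc = x.data - mu.reshape(1, c, 1, 1)
    var = np.mean(xc * xc, axis=(0, 2, 3))
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv.reshape(1, c, 1, 1)
    y = xhat * gamma.data.reshape(1, c, 1, 1) + beta.data.reshape(1, c, 1, 1)
    out = _make(y, (x, gamma, beta))
    if out._parents:
        def bw(g, x=x, gamma=gamma, beta=beta, xhat=xhat, inv=inv):
            beta._accum(g.sum(axis=(0, 2, 3)))
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if x.requires_grad or x._parents:
                gx = g * gamma.data.reshape(1, c, 1, 1)
                s1 = gx.sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
                s2 = (gx * xhat).sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
                dx = (gx - s1 / m - xhat * (s2 / m)) * inv.reshape(1, c, 1, 1)
                x._accum(dx)
        out._backward = bw
    return out, mu, var


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Interpolation matrix for half-pixel-center bilinear resampling."""
    a = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        t = src - i0
        a[i, i0] += 1.0 - t
        a[i, i1] += t
    return a


_BILINEAR_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _bmat(n_out: int, n_in: int) -> np.ndarray:
    key = (n_out, n_in)
    if key not in _BILINEAR_CACHE:
        _BILINEAR_CACHE[key] = _bilinear_matrix(n_out, n_in)
    return _BILINEAR_CACHE[key]


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    """Bilinear upsampling by an integer factor, half-pixel-center convention."""
    n, c, h, w = x.data.shape
    ar = _bmat(h * factor, h)
    ac = _bmat(w * factor, w)
    y = np.matmul(np.matmul(ar[None, None], x.data), ac.T)
    out = _make(y, (x,))
    if out._parents:
        def bw(g, x=x, ar=ar, ac=ac):
            x._accum(np.matmul(np.matmul(ar.T[None, None], g), ac))
        out._backward = bw
    return out
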