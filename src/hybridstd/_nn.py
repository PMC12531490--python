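"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the two network architectures in this
package need: broadcast arithmetic, matmul, 2-D convolution (im2col),
depthwise temporal convolution, batch normalisation, ELU/sigmoid/softmax,
dropout masks, reductions, slicing/concatenation, and an Adam optimiser.
Gradients are checked against central finite differences in the test
suite; all computation is pure numpy and therefore deterministic.
"""

from __future__ import annotations

import numpy as np

#: compute dtype for all tensors; float32 is the working precision, tests
#: switch to float64 when comparing against finite differences
DTYPE = np.float32


def set_dtype(dt) -> None:
    global DTYPE
    DTYPE = np.dtype(dt).type


__all__ = [
    "DTYPE",
    "set_dtype",
    "Tensor",
    "concat",
    "conv2d",
    "depthwise_conv1d",
    "softmax",
    "softmax_cross_entropy",
    "Conv2d",
    "DepthwiseConv1d",
    "Linear",
    "BatchNorm",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- helpers -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad)
        out._prev = (self, other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad)
        out._prev = (self, other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other._pow(-1.0)

    def _pow(self, p: float):
        out = Tensor(np.power(self.data, p), self.requires_grad)
        out._prev = (self,)

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * np.power(self.data, p - 1.0))

        out._backward = bw
        return out

    def __pow__(self, p):
        return self._pow(float(p))

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, self.requires_grad or other.requires_grad)
        out._prev = (self, other)

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bw
        return out

    __matmul__ = matmul

    # -- reductions / shaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad)
        out._prev = (self,)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad)
        out._prev = (self,)

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), self.requires_grad)
        out._prev = (self,)
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        out._backward = bw
        return out

    def slice(self, idx):
        out = Tensor(self.data[idx], self.requires_grad)
        out._prev = (self,)

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accum(full)

        out._backward = bw
        return out

    # -- nonlinearities ----------------------------------------------------
    def elu(self):
        x = self.data
        xn = np.minimum(x, 0.0)
        y = np.where(x > 0, x, np.expm1(xn))
        out = Tensor(y, self.requires_grad)
        out._prev = (self,)

        def bw(g):
            if self.requires_grad:
                self._accum(g * np.where(x > 0, 1.0, np.exp(xn)))

        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, self.requires_grad)
        out._prev = (self,)

        def bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = bw
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad)
        out._prev = (self,)

        def bw(g):
            if self.requires_grad:
                self._accum(g * e)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad)
        out._prev = (self,)

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bw
        return out

    # -- autodiff ----------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def build(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                build(p)
            topo.append(t)

        build(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def concat(tensors, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), any(t.requires_grad for t in tensors))
    out._prev = tuple(tensors)
    sizes = [d.shape[axis] for d in datas]

    def bw(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(start, start + s)
                t._accum(g[tuple(idx)])
            start += s

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int, ph: int, pw: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    s0, s1, s2, s3 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * sh, s3 * sw),
        writeable=False,
    )
    return cols, ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=(1, 1), pad=(0, 0)) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    x: (N, C, H, W); w: (F, C, kh, kw); b: (F,) or None.
    """
    sh, sw = stride
    ph, pw = pad
    f, c, kh, kw = w.data.shape
    n = x.data.shape[0]
    cols, ho, wo = _im2col(x.data, kh, kw, sh, sw, ph, pw)
    # contiguous (N, C*kh*kw, Ho*Wo) patch matrix; one copy, then GEMMs
    cols2 = cols.reshape(n, c * kh * kw, ho * wo)
    wmat = w.data.reshape(f, -1)
    y = np.matmul(wmat[None], cols2).reshape(n, f, ho, wo)
    if b is not None:
        y = y + b.data[None, :, None, None]
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    out = Tensor(y, req)
    out._prev = (x, w) if b is None else (x, w, b)

    def bw(g):
        g2 = np.ascontiguousarray(g.reshape(n, f, ho * wo))
        if w.requires_grad:
            dw = np.matmul(g2, cols2.transpose(0, 2, 1)).sum(axis=0)
            w._accum(dw.reshape(f, c, kh, kw))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            h, wd = x.data.shape[2], x.data.shape[3]
            dcols = np.matmul(wmat.T[None], g2).reshape(n, c, kh, kw, ho, wo)
            dxp = np.zeros((n, c, h + 2 * ph, wd + 2 * pw), dtype=g.dtype)
            for a in range(kh):
                for bk in range(kw):
                    dxp[:, :, a:a + sh * ho:sh, bk:bk + sw * wo:sw] += \
                        dcols[:, :, a, bk]
            if ph or pw:
                dxp = dxp[:, :, ph:ph + h, pw:pw + wd]
            x._accum(dxp)

    out._backward = bw
    return out


def depthwise_conv1d(x: Tensor, w: Tensor, pad: int) -> Tensor:
    """Per-channel temporal convolution on (N, C, H, W) along W.

    w: (C, k) — one kernel per channel, shared over H; 'same'-style padding
    when pad == k//2 and k odd.
    """
    c, k = w.data.shape
    n, cx, h, t = x.data.shape
    if cx != c:
        raise ValueError("channel mismatch in depthwise conv")
    xp = np.pad(x.data, ((0, 0), (0, 0), (0, 0), (pad, pad)))
    to = t + 2 * pad - k + 1
    y = np.zeros((n, c, h, to), dtype=x.data.dtype)
    for a in range(k):
        y += w.data[None, :, None, a:a + 1] * xp[:, :, :, a:a + to]
    out = Tensor(y, x.requires_grad or w.requires_grad)
    out._prev = (x, w)

    def bw(g):
        if w.requires_grad:
            dw = np.empty((c, k), dtype=g.dtype)
            for a in range(k):
                dw[:, a] = (g * xp[:, :, :, a:a + to]).sum(axis=(0, 2, 3))
            w._accum(dw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for a in range(k):
                dxp[:, :, :, a:a + to] += w.data[None, :, None, a:a + 1] * g
            x._accum(dxp[:, :, :, pad:pad + t])

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# softmax / loss
# ---------------------------------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, x.requires_grad)
    out._prev = (x,)

    def bw(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accum(s * (g - dot))

    out._backward = bw
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy between softmax(logits) and integer labels."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None)).mean()
    out = Tensor(nll, logits.requires_grad)
    out._prev = (logits,)

    def bw(g):
        if logits.requires_grad:
            d = p.copy()
            d[np.arange(n), labels] -= 1.0
            logits._accum(g * d / n)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _iter_children(obj):
    for v in obj.__dict__.values():
        if isinstance(v, (list, tuple)):
            yield from v
        elif isinstance(v, dict):
            yield from v.values()
        else:
            yield v


class Module:
    def parameters(self) -> list[Tensor]:
        ps = []
        for v in _iter_children(self):
            if isinstance(v, Tensor) and v.requires_grad:
                ps.append(v)
            elif isinstance(v, Module):
                ps.extend(v.parameters())
        return ps

    def state(self) -> list[np.ndarray]:
        """Copy of all parameter arrays plus running statistics."""
        out = [p.data.copy() for p in self.parameters()]
        out.extend(a.copy() for a in self._buffers())
        return out

    def load_state(self, arrays: list[np.ndarray]) -> None:
        ps = self.parameters()
        for p, a in zip(ps, arrays[: len(ps)]):
            p.data[...] = a
        for buf, a in zip(self._buffers(), arrays[len(ps):]):
            buf[...] = a

    def _buffers(self) -> list[np.ndarray]:
        bs = []
        for v in _iter_children(self):
            if isinstance(v, BatchNorm):
                bs.extend([v.running_mean, v.running_var])
            elif isinstance(v, Module):
                bs.extend(v._buffers())
        return bs


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class Conv2d(Module):
    def __init__(self, in_c, out_c, kh, kw, rng, stride=(1, 1), pad=(0, 0), bias=True):
        fan_in = in_c * kh * kw
        self.w = Tensor(_glorot(rng, (out_c, in_c, kh, kw), fan_in, out_c * kh * kw),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_c), requires_grad=True) if bias else None
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.stride, self.pad)


class DepthwiseConv1d(Module):
    def __init__(self, channels, k, rng):
        self.w = Tensor(_glorot(rng, (channels, k), k, k), requires_grad=True)
        self.pad = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return depthwise_conv1d(x, self.w, self.pad)


class Linear(Module):
    def __init__(self, n_in, n_out, rng):
        self.w = Tensor(_glorot(rng, (n_in, n_out), n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class BatchNorm(Module):
    """Batch normalisation over all axes except the channel axis (axis 1)."""

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        axes = (0,) + tuple(range(2, x.ndim))
        bshape = (1, -1) + (1,) * (x.ndim - 2)
        if train:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            self.running_mean += self.momentum * (mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (var.data.reshape(-1) - self.running_var)
            inv = (var + self.eps) ** (-0.5)
            xn = xc * inv
        else:
            mu = self.running_mean.reshape(bshape)
            inv = 1.0 / np.sqrt(self.running_var.reshape(bshape) + self.eps)
            xn = (x - Tensor(mu)) * Tensor(inv)
        return xn * self.gamma.reshape(*bshape) + self.beta.reshape(*bshape)


class Adam:
    def __init__(self, params: list[Tensor], lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
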