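"""Reverse-mode automatic differentiation on numpy arrays.

This is the numerical core of the package: a small tape-based autograd
engine providing exactly the operations the segmentation network needs —
dilated 2-D convolution, 2x2 transposed convolution, 2x2 max-pooling,
batch normalization, ReLU/sigmoid, channel concatenation and the
elementwise/reduction arithmetic required by the soft Dice loss.  Every
operation records a closure that propagates the upstream gradient to its
inputs; ``Tensor.backward`` runs them in reverse topological order.

All computation is plain numpy, so runs are deterministic given fixed
seeds: there are no nondeterministic kernels to disable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Module",
    "Sequential",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "relu",
    "sigmoid",
    "conv2d",
    "conv_transpose2x2",
    "max_pool2x2",
    "concat_channels",
    "global_avg_pool",
    "soft_dice_loss",
]

DEFAULT_DTYPE = np.float32


def _as_array(data, dtype=None):
    a = np.asarray(data)
    if a.dtype.kind != "f":
        a = a.astype(dtype or DEFAULT_DTYPE)
    return a


class Tensor:
    """An n-d array with an optional gradient and a backward closure.

    ``requires_grad`` is sticky for leaves and propagates through
    operations: a result requires a gradient iff any input does.
    Gradients of non-requiring tensors are never materialized.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = _as_array(data)
        self.grad = None
        self._parents = _parents
        self._backward = _backward
        if _parents and not requires_grad:
            requires_grad = any(p.requires_grad for p in _parents)
        self.requires_grad = requires_grad

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def build(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                build(p)
            topo.append(t)

        build(self)
        _accum(self, np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __truediv__(self, other):
        return div(self, other)

    def __pow__(self, p):
        return power(self, p)

    def sum(self, axis=None, keepdims=False):
        return tensor_sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return tensor_sum(self, axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        return reshape(self, shape)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t, g):
    """Accumulate gradient g into tensor t (if it participates in autograd)."""
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g  # closures always hand over fresh or read-only arrays
    else:
        t.grad = t.grad + g


def _unbroadcast(g, shape):
    """Sum-reduce gradient g back to the given broadcast-source shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / reduction ops
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, _parents=(a, b))

    def _bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    out._backward = _bw
    return out


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, _parents=(a, b))

    def _bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    out._backward = _bw
    return out


def div(a, b):
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data / b.data, _parents=(a, b))

    def _bw(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    out._backward = _bw
    return out


def power(a, p):
    a = _wrap(a)
    out = Tensor(a.data ** p, _parents=(a,))

    def _bw(g):
        _accum(a, g * p * a.data ** (p - 1))

    out._backward = _bw
    return out


def tensor_sum(a, axis=None, keepdims=False):
    a = _wrap(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), _parents=(a,))

    def _bw(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape))

    out._backward = _bw
    return out


def reshape(a, shape):
    a = _wrap(a)
    out = Tensor(a.data.reshape(shape), _parents=(a,))

    def _bw(g):
        _accum(a, g.reshape(a.data.shape))

    out._backward = _bw
    return out


def relu(a):
    a = _wrap(a)
    mask = a.data > 0
    out = Tensor(a.data * mask, _parents=(a,))

    def _bw(g):
        _accum(a, g * mask)

    out._backward = _bw
    return out


def sigmoid(a):
    a = _wrap(a)
    # numerically stable logistic
    s = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.data))),
                 np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))
    out = Tensor(s, _parents=(a,))

    def _bw(g):
        _accum(a, g * s * (1.0 - s))

    out._backward = _bw
    return out


def concat_channels(a, b):
    """Concatenate two NCHW tensors along the channel axis."""
    a, b = _wrap(a), _wrap(b)
    ca = a.data.shape[1]
    out = Tensor(np.concatenate([a.data, b.data], axis=1), _parents=(a, b))

    def _bw(g):
        _accum(a, g[:, :ca])
        _accum(b, g[:, ca:])

    out._backward = _bw
    return out


def global_avg_pool(a):
    """Mean over the spatial axes of an NCHW tensor, keeping dims (N,C,1,1)."""
    a = _wrap(a)
    n = a.data.shape[2] * a.data.shape[3]
    return tensor_sum(a, axis=(2, 3), keepdims=True) * (1.0 / float(n))


# ---------------------------------------------------------------------------
# convolution / pooling
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None, dilation=1, padding=None):
    """2-D convolution (stride 1) with optional dilation, 'same' padding.

    x: (N, C, H, W);  w: (O, C, k, k);  b: (O,) or None.
    The effective kernel extent is (k-1)*dilation + 1; default padding
    keeps the spatial size unchanged for odd k.
    """
    x, w = _wrap(x), _wrap(w)
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    O, _, k, _ = wd.shape
    d = int(dilation)
    ke = (k - 1) * d + 1
    p = (ke - 1) // 2 if padding is None else int(padding)

    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
    Ho = H + 2 * p - ke + 1
    Wo = W + 2 * p - ke + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(f"kernel extent {ke} exceeds padded input {H + 2 * p}x{W + 2 * p}")

    # channel-first layout so every kernel tap is one contiguous matmul
    xpc = np.ascontiguousarray(xp.transpose(1, 0, 2, 3))  # (C, N, Hp, Wp)
    Hp, Wp = xpc.shape[2], xpc.shape[3]
    xflat = xpc.reshape(C, N * Hp * Wp)

    if k == 1:
        acc = (wd[:, :, 0, 0] @ xflat).reshape(O, N, Hp, Wp)
    else:
        wtap = wd.transpose(2, 3, 0, 1).reshape(k * k * O, C)
        T = (wtap @ xflat).reshape(k, k, O, N, Hp, Wp)
        acc = np.zeros((O, N, Ho, Wo), dtype=T.dtype)
        for a_ in range(k):
            for b_ in range(k):
                acc += T[a_, b_, :, :, a_ * d:a_ * d + Ho, b_ * d:b_ * d + Wo]
    out = np.ascontiguousarray(acc.transpose(1, 0, 2, 3))
    if b is not None:
        out = out + b.data.reshape(1, O, 1, 1)

    parents = (x, w) + ((b,) if b is not None else ())
    res = Tensor(out, _parents=parents)

    def _bw(g):
        gc = np.ascontiguousarray(g.transpose(1, 0, 2, 3))  # (O, N, Ho, Wo)
        gflat = gc.reshape(O, N * Ho * Wo)
        if w.requires_grad:
            gw = np.empty_like(wd)
            for a_ in range(k):
                for b_ in range(k):
                    xs = xpc[:, :, a_ * d:a_ * d + Ho, b_ * d:b_ * d + Wo]
                    gw[:, :, a_, b_] = gflat @ xs.reshape(C, N * Ho * Wo).T
            _accum(w, gw)
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            if k == 1:
                gxc = (wd[:, :, 0, 0].T @ gflat).reshape(C, N, Ho, Wo)
            else:
                wtap_t = wd.transpose(2, 3, 1, 0).reshape(k * k * C, O)
                U = (wtap_t @ gflat).reshape(k, k, C, N, Ho, Wo)
                gxpc = np.zeros_like(xpc)
                for a_ in range(k):
                    for b_ in range(k):
                        gxpc[:, :, a_ * d:a_ * d + Ho, b_ * d:b_ * d + Wo] += U[a_, b_]
                gxc = gxpc[:, :, p:p + H, p:p + W] if p else gxpc
            gx = np.ascontiguousarray(gxc.transpose(1, 0, 2, 3))
            _accum(x, gx)

    res._backward = _bw
    return res


def conv_transpose2x2(x, w, b=None):
    """Transposed convolution, kernel 2, stride 2 (spatial size doubles).

    x: (N, C, H, W);  w: (C, O, 2, 2);  output: (N, O, 2H, 2W).
    """
    x, w = _wrap(x), _wrap(w)
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    O = wd.shape[1]
    # y[n,o,2h+i,2w+j] = sum_c x[n,c,h,w] * w[c,o,i,j]
    y6 = np.einsum("nchw,coij->nohiwj", xd, wd, optimize=True)
    out = y6.reshape(N, O, 2 * H, 2 * W)
    if b is not None:
        out = out + b.data.reshape(1, O, 1, 1)

    parents = (x, w) + ((b,) if b is not None else ())
    res = Tensor(out, _parents=parents)

    def _bw(g):
        g6 = g.reshape(N, O, H, 2, W, 2)
        if x.requires_grad:
            _accum(x, np.einsum("nohiwj,coij->nchw", g6, wd, optimize=True))
        if w.requires_grad:
            _accum(w, np.einsum("nchw,nohiwj->coij", xd, g6, optimize=True))
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))

    res._backward = _bw
    return res


def max_pool2x2(x):
    """2x2 max pooling, stride 2; requires even H and W."""
    x = _wrap(x)
    xd = x.data
    N, C, H, W = xd.shape
    if H % 2 or W % 2:
        raise ValueError(f"max_pool2x2 needs even spatial dims, got {H}x{W}")
    Ho, Wo = H // 2, W // 2
    xf = xd.reshape(N, C, Ho, 2, Wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, Ho, Wo, 4)
    idx = xf.argmax(axis=-1)
    out = np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0]
    res = Tensor(out, _parents=(x,))

    def _bw(g):
        if x.requires_grad:
            gf = np.zeros((N, C, Ho, Wo, 4), dtype=g.dtype)
            np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
            gx = gf.reshape(N, C, Ho, Wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
            _accum(x, gx)

    res._backward = _bw
    return res


def batch_norm(x, gamma, beta, running_mean, running_var, training,
               momentum=0.1, eps=1e-5):
    """Per-channel batch normalization over an NCHW tensor.

    In training mode normalizes with batch statistics and updates the
    running buffers in place; in evaluation mode uses the buffers.
    """
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    xd = x.data
    N, C, H, W = xd.shape
    gsh = (1, C, 1, 1)

    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var

    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu.reshape(gsh)) * inv_std.reshape(gsh)
    out = Tensor(gamma.data.reshape(gsh) * xhat + beta.data.reshape(gsh),
                 _parents=(x, gamma, beta))

    def _bw(g):
        if gamma.requires_grad:
            _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            _accum(beta, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxhat = g * gamma.data.reshape(gsh)
            if training:
                m = N * H * W
                s1 = gxhat.sum(axis=(0, 2, 3)).reshape(gsh)
                s2 = (gxhat * xhat).sum(axis=(0, 2, 3)).reshape(gsh)
                gx = (inv_std.reshape(gsh) / m) * (m * gxhat - s1 - xhat * s2)
            else:
                gx = gxhat * inv_std.reshape(gsh)
            _accum(x, gx)

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def soft_dice_loss(pred, truth, eps=1e-6):
    """Differentiable Dice loss, averaged over the images of a batch.

    Per image: 1 - (2 * sum(y * y_hat) + eps) / (sum(y^2) + sum(y_hat^2) + eps)
    where y is the binary ground truth and y_hat the predicted lesion
    probability.  ``eps`` keeps the ratio defined on lesion-free images;
    eps=0 recovers the exact closed form.
    """
    pred = _wrap(pred)
    t = Tensor(np.asarray(truth, dtype=pred.data.dtype).reshape(pred.data.shape))
    axes = tuple(range(1, pred.ndim))
    num = tensor_sum(mul(pred, t), axis=axes)
    den = add(tensor_sum(power(pred, 2), axis=axes), tensor_sum(power(t, 2), axis=axes))
    ratio = div(add(mul(num, 2.0), eps), add(den, eps))
    per_image = add(1.0, -ratio)
    return per_image.mean()


# ---------------------------------------------------------------------------
# module system
# ---------------------------------------------------------------------------

class Module:
    """Base class with parameter discovery, train/eval mode and state dicts.

    Child modules and parameters are discovered by scanning instance
    attributes (lists of modules included), in insertion order, which
    makes parameter ordering — and hence optimization — deterministic.
    """

    _buffer_names: tuple = ()

    def __init__(self):
        self.training = True

    # attribute scans ------------------------------------------------------
    def _items(self):
        for name, v in self.__dict__.items():
            if isinstance(v, (Module, Tensor)):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, u in enumerate(v):
                    if isinstance(u, (Module, Tensor)):
                        yield f"{name}.{i}", u

    def named_parameters(self, prefix=""):
        for name, v in self._items():
            if isinstance(v, Tensor):
                if v.requires_grad:
                    yield prefix + name, v
            else:
                yield from v.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix=""):
        for bn in self._buffer_names:
            yield prefix + bn, getattr(self, bn)
        for name, v in self._items():
            if isinstance(v, Module):
                yield from v.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for _, v in self._items():
            if isinstance(v, Module):
                yield from v.modules()

    # mode -----------------------------------------------------------------
    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # state ------------------------------------------------------------------
    def state_dict(self):
        sd = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            sd[name] = np.array(buf, copy=True)
        return sd

    def load_state_dict(self, sd):
        for name, p in self.named_parameters():
            p.data = np.array(sd[name], dtype=p.data.dtype, copy=True)
        for name, buf in self.named_buffers():
            buf[...] = sd[name]

    def num_parameters(self):
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """Stride-1 2-D convolution layer with He-normal initialization."""

    def __init__(self, in_channels, out_channels, kernel_size, rng,
                 dilation=1, bias=True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size)
                       ).astype(DEFAULT_DTYPE),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=DEFAULT_DTYPE),
                           requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, dilation=self.dilation)


class ConvTranspose2d(Module):
    """Kernel-2, stride-2 transposed convolution (doubles H and W)."""

    def __init__(self, in_channels, out_channels, rng, bias=True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        std = np.sqrt(2.0 / (in_channels * 4))
        self.weight = Tensor(
            rng.normal(0.0, std, (in_channels, out_channels, 2, 2)).astype(DEFAULT_DTYPE),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=DEFAULT_DTYPE),
                           requires_grad=True) if bias else None

    def forward(self, x):
        return conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.weight = Tensor(np.ones(channels, dtype=DEFAULT_DTYPE), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=DEFAULT_DTYPE), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def forward(self, x):
        return batch_norm(x, self.weight, self.bias, self.running_mean,
                          self.running_var, self.training,
                          momentum=self.momentum, eps=self.eps)
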