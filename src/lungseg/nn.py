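"""A compact reverse-mode autodiff engine for CPU training of small
convolutional networks.

Arrays are NCHW float32 (float64 selectable for gradient checking).
Convolutions run as im2col + one BLAS GEMM per layer; every op records a
closure that accumulates gradients into its inputs, and ``Tensor.backward``
replays them in reverse topological order. Only the ops needed by the
segmentation network are provided; the engine is deliberately minimal and
fully deterministic given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad=False, _prev=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = tuple(_prev)
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad:
        t.grad = g if t.grad is None else t.grad + g


# --------------------------------------------------------------------------
# im2col / col2im

def _im2col(xd, kh, kw, stride, pad):
    n, c, h, w = xd.shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else xd
    cols = np.empty((c, kh, kw, n, oh, ow), dtype=xd.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, i, j] = xp[
                :, :, i : i + stride * oh : stride, j : j + stride * ow : stride
            ].transpose(1, 0, 2, 3)
    return cols.reshape(c * kh * kw, n * oh * ow), oh, ow


def _col2im(dcols2, xshape, kh, kw, stride, pad, oh, ow):
    n, c, h, w = xshape
    dcols = dcols2.reshape(c, kh, kw, n, oh, ow)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols2.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[
                :, :, i : i + stride * oh : stride, j : j + stride * ow : stride
            ] += dcols[:, i, j].transpose(1, 0, 2, 3)
    return dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp


# --------------------------------------------------------------------------
# ops

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, padding=0) -> Tensor:
    cout, cin, kh, kw = w.data.shape
    if x.data.shape[1] != cin:
        raise ValueError(f"conv2d: expected {cin} input channels, got {x.data.shape[1]}")
    cols2, oh, ow = _im2col(x.data, kh, kw, stride, padding)
    w2 = w.data.reshape(cout, -1)
    y2 = w2 @ cols2
    if b is not None:
        y2 += b.data[:, None]
    n = x.data.shape[0]
    out = y2.reshape(cout, n, oh, ow).transpose(1, 0, 2, 3)
    prev = (x, w) + (() if b is None else (b,))

    def bwd(g):
        dy2 = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(cout, -1)
        if w.requires_grad:
            _accum(w, (dy2 @ cols2.T).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            _accum(b, dy2.sum(axis=1))
        if x.requires_grad:
            _accum(
                x,
                _col2im(w2.T @ dy2, x.data.shape, kh, kw, stride, padding, oh, ow),
            )

    return Tensor(out, _prev=prev, _backward=bwd)


def batchnorm2d(x, gamma, beta, running_mean, running_var, training, momentum=0.1,
                eps=1e-5):
    """Returns (out, new_running_mean, new_running_var)."""
    xd = x.data
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        new_rm = (1 - momentum) * running_mean + momentum * mu
        new_rv = (1 - momentum) * running_var + momentum * var
    else:
        mu, var = running_mean, running_var
        new_rm, new_rv = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu[None, :, None, None]) * invstd[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    m = xd.shape[0] * xd.shape[2] * xd.shape[3]

    def bwd(g):
        if gamma.requires_grad:
            _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            _accum(beta, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gam = gamma.data[None, :, None, None]
            istd = invstd[None, :, None, None]
            if training:
                dxhat = g * gam
                s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                _accum(x, istd / m * (m * dxhat - s1 - xhat * s2))
            else:
                _accum(x, g * gam * istd)

    return Tensor(out, _prev=(x, gamma, beta), _backward=bwd), new_rm, new_rv


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0)

    def bwd(g):
        if x.requires_grad:
            _accum(x, g * (x.data > 0))

    return Tensor(out, _prev=(x,), _backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    s = expit(x.data)

    def bwd(g):
        if x.requires_grad:
            _accum(x, g * s * (1 - s))

    return Tensor(s, _prev=(x,), _backward=bwd)


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)

    def bwd(g):
        if x.requires_grad:
            _accum(x, g * (1 - t * t))

    return Tensor(t, _prev=(x,), _backward=bwd)


def add(x: Tensor, y: Tensor) -> Tensor:
    if x.data.shape != y.data.shape:
        raise ValueError(f"add: shape mismatch {x.data.shape} vs {y.data.shape}")

    def bwd(g):
        _accum(x, g)
        _accum(y, g)

    return Tensor(x.data + y.data, _prev=(x, y), _backward=bwd)


def mul(x: Tensor, y: Tensor) -> Tensor:
    if x.data.shape != y.data.shape:
        raise ValueError(f"mul: shape mismatch {x.data.shape} vs {y.data.shape}")

    def bwd(g):
        if x.requires_grad:
            _accum(x, g * y.data)
        if y.requires_grad:
            _accum(y, g * x.data)

    return Tensor(x.data * y.data, _prev=(x, y), _backward=bwd)


def concat(tensors, axis=1) -> Tensor:
    tensors = list(tensors)
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def bwd(g):
        start = 0
        for t, size in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + size)
            _accum(t, g[tuple(sl)])
            start += size

    return Tensor(out, _prev=tuple(tensors), _backward=bwd)


def narrow(x: Tensor, start: int, length: int, axis: int = 1) -> Tensor:
    sl = [slice(None)] * x.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)
    out = x.data[sl]

    def bwd(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            dx[sl] = g
            _accum(x, dx)

    return Tensor(out, _prev=(x,), _backward=bwd)


def maxpool2d(x: Tensor, kernel=2, stride=None, padding=0) -> Tensor:
    stride = stride or kernel
    n, c, h, w = x.data.shape
    oh = (h + 2 * padding - kernel) // stride + 1
    ow = (w + 2 * padding - kernel) // stride + 1
    neg = np.finfo(x.data.dtype).min
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2),
               constant_values=neg)
        if padding
        else x.data
    )
    windows = np.empty((kernel * kernel, n, c, oh, ow), dtype=x.data.dtype)
    for i in range(kernel):
        for j in range(kernel):
            windows[i * kernel + j] = xp[
                :, :, i : i + stride * oh : stride, j : j + stride * ow : stride
            ]
    arg = windows.argmax(axis=0)
    out = windows.max(axis=0)

    def bwd(g):
        if not x.requires_grad:
            return
        dxp = np.zeros_like(xp)
        for i in range(kernel):
            for j in range(kernel):
                mask = arg == (i * kernel + j)
                dxp[
                    :, :, i : i + stride * oh : stride, j : j + stride * ow : stride
                ] += g * mask
        _accum(
            x,
            dxp[:, :, padding : padding + h, padding : padding + w]
            if padding
            else dxp,
        )

    return Tensor(out, _prev=(x,), _backward=bwd)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bwd(g):
        if x.requires_grad:
            n, c, h2, w2 = g.shape
            _accum(x, g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return Tensor(out, _prev=(x,), _backward=bwd)


# --------------------------------------------------------------------------
# losses (scalar outputs; targets are plain arrays)

def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    z, t = logits.data, np.asarray(target, dtype=logits.data.dtype)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out = loss.mean()

    def bwd(g):
        if logits.requires_grad:
            _accum(logits, g * (expit(z) - t) / z.size)

    return Tensor(out, _prev=(logits,), _backward=bwd)


def soft_dice_loss(probs: Tensor, target: np.ndarray, smooth=1.0) -> Tensor:
    p, t = probs.data, np.asarray(target, dtype=probs.data.dtype)
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum() + smooth)
    out = 1.0 - (2.0 * inter + smooth) / denom

    def bwd(g):
        if probs.requires_grad:
            _accum(probs, g * -(2.0 * t * denom - (2.0 * inter + smooth)) / denom**2)

    return Tensor(np.asarray(out, dtype=p.dtype), _prev=(probs,), _backward=bwd)


# --------------------------------------------------------------------------
# modules

class Module:
    """Base with recursive parameter collection and train/eval switching."""

    training: bool = True

    def parameters(self):
        params, seen = [], set()

        def collect(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def _submodules(self):
        for v in vars(self).values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                yield from (m for m in v if isinstance(m, Module))

    def train(self, mode=True):
        self.training = mode
        for m in self._submodules():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def he_init(rng, shape, fan_in, dtype):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2D(Module):
    def __init__(self, cin, cout, kernel=3, stride=1, padding="same", bias=True,
                 rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        if padding == "same":
            padding = (kernel - 1) // 2
        self.stride, self.padding = stride, padding
        self.weight = Parameter(
            he_init(rng, (cout, cin, kernel, kernel), cin * kernel * kernel, dtype)
        )
        self.bias = Parameter(np.zeros(cout, dtype=dtype)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2D(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=np.float32):
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor) -> Tensor:
        out, rm, rv = batchnorm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )
        self.running_mean = rm.astype(self.running_mean.dtype)
        self.running_var = rv.astype(self.running_var.dtype)
        return out


class ConvLSTM2D(Module):
    """Convolutional LSTM over a (short) sequence of NCHW feature maps.

    One convolution over [x_t, h_{t-1}] produces the four gate pre-activations
    (input, forget, output, candidate); state starts at zero.
    """

    def __init__(self, cin, hidden, kernel=3, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        if kernel % 2 != 1:
            raise ValueError("ConvLSTM kernel must be odd")
        self.hidden = hidden
        self.conv = Conv2D(cin + hidden, 4 * hidden, kernel, rng=rng, dtype=dtype)

    def __call__(self, sequence) -> Tensor:
        """Process the sequence in order; returns the final hidden state."""
        first = sequence[0]
        n, _, hgt, wid = first.data.shape
        hzero = np.zeros((n, self.hidden, hgt, wid), dtype=first.data.dtype)
        h = Tensor(hzero)
        c = Tensor(hzero.copy())
        for x_t in sequence:
            z = self.conv(concat([x_t, h], axis=1))
            hsz = self.hidden
            i = sigmoid(narrow(z, 0 * hsz, hsz))
            f = sigmoid(narrow(z, 1 * hsz, hsz))
            o = sigmoid(narrow(z, 2 * hsz, hsz))
            g = tanh(narrow(z, 3 * hsz, hsz))
            c = add(mul(f, c), mul(i, g))
            h = mul(o, tanh(c))
        return h


class BConvLSTMFusion(Module):
    """Bidirectional ConvLSTM fusion of an encoder and a decoder feature map.

    The two maps form a length-2 sequence (encoder first); a forward
    ConvLSTM reads it in order, an independent backward ConvLSTM reads it
    reversed, and the two final hidden states are concatenated, giving
    2 x channels output channels.
    """

    def __init__(self, channels, kernel=3, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.forward_lstm = ConvLSTM2D(channels, channels, kernel, rng=rng, dtype=dtype)
        self.backward_lstm = ConvLSTM2D(channels, channels, kernel, rng=rng, dtype=dtype)

    def __call__(self, encoder_map: Tensor, decoder_map: Tensor) -> Tensor:
        if encoder_map.data.shape != decoder_map.data.shape:
            raise ValueError(
                f"BConvLSTM fusion requires equal shapes, got "
                f"{encoder_map.data.shape} vs {decoder_map.data.shape}"
            )
        h_fwd = self.forward_lstm([encoder_map, decoder_map])
        h_bwd = self.backward_lstm([decoder_map, encoder_map])
        return concat([h_fwd, h_bwd], axis=1)


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        # bias-corrected update folded into scalars to avoid large temporaries
        corr2 = np.sqrt(1 - b2**self.t)
        alpha = self.lr * corr2 / (1 - b1**self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            g *= g  # grad buffer is consumed; reuse it as scratch
            g *= 1 - b2
            v += g
            np.sqrt(v, out=g)
            g += self.eps * corr2
            np.divide(m, g, out=g)
            g *= alpha
            p.data -= g
            p.grad = None
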