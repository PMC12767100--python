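"""Neural-network layers built on the autodiff core.

Convolutions are expressed as sums of shifted matrix products (one GEMM per
kernel tap), which keeps the graph small and lets BLAS do the heavy lifting.
All parameters are float64 Tensors initialised from a caller-supplied
``numpy.random.Generator`` so model construction is fully seeded.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: children registered as attributes contribute parameters."""

    def parameters(self):
        params = []

        def visit(v):
            if isinstance(v, Tensor):
                if v.requires_grad:
                    params.append(v)
            elif isinstance(v, Module):
                for child in v.__dict__.values():
                    visit(child)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    visit(item)

        visit(self)
        return params

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng, shape, std):
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in, n_out, rng):
        self.weight = _param(rng, (n_in, n_out), np.sqrt(2.0 / n_in))
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x):
        return ag.add(ag.matmul(x, self.weight), self.bias)


class Conv1d(Module):
    """Same-padded stride-1 1D convolution over (channels, length)."""

    def __init__(self, c_in, c_out, kernel, rng):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        std = np.sqrt(2.0 / (c_in * kernel))
        self.weight = _param(rng, (kernel, c_out, c_in), std)
        self.bias = Tensor(np.zeros((c_out, 1)), requires_grad=True)

    def forward(self, x):
        return ag.conv1d(x, self.weight, self.bias)


class Conv2d3x3(Module):
    """Same-padded stride-1 3x3 convolution with dilation, over (C, H, W)."""

    def __init__(self, c_in, c_out, rng, dilation=1):
        self.dilation = int(dilation)
        std = np.sqrt(2.0 / (c_in * 9))
        self.weight = _param(rng, (9, c_out, c_in), std)
        self.bias = Tensor(np.zeros((c_out, 1)), requires_grad=True)
        self.c_out = c_out

    def forward(self, x):
        return ag.conv2d3x3(x, self.weight, self.bias, self.dilation)


class Conv2d1x1(Module):
    def __init__(self, c_in, c_out, rng):
        self.weight = _param(rng, (c_out, c_in), np.sqrt(2.0 / c_in))
        self.bias = Tensor(np.zeros((c_out, 1)), requires_grad=True)
        self.c_out = c_out

    def forward(self, x):
        c_in, h, w = x.shape
        flat = ag.reshape(x, (c_in, h * w))
        out = ag.add(ag.matmul(self.weight, flat), self.bias)
        return ag.reshape(out, (self.c_out, h, w))


def avg_pool1d(x, factor):
    """Mean-pool (channels, length) by an integer factor."""
    c, length = x.shape
    if length % factor != 0:
        raise ValueError(f"length {length} not divisible by pool factor {factor}")
    return ag.mean(ag.reshape(x, (c, length // factor, factor)), axis=2)


def avg_pool2d(x, factor=2):
    c, h, w = x.shape
    if h % factor or w % factor:
        raise ValueError("spatial dims not divisible by pool factor")
    r = ag.reshape(x, (c, h // factor, factor, w // factor, factor))
    return ag.mean(r, axis=(2, 4))


def upsample2d(x, factor=2):
    return ag.repeat2d(x, factor)


class LSTM(Module):
    """Single-layer bidirectional LSTM over a (T, n_in) sequence.

    Returns the concatenated per-step hidden states, shape (T, 2 * hidden).
    Forget-gate bias starts at 1 (standard stabilisation).
    """

    def __init__(self, n_in, hidden, rng):
        self.hidden = hidden
        s = 1.0 / np.sqrt(hidden)
        self.wx_f = Tensor(rng.uniform(-s, s, (n_in, 4 * hidden)), requires_grad=True)
        self.wh_f = Tensor(rng.uniform(-s, s, (hidden, 4 * hidden)), requires_grad=True)
        self.b_f = Tensor(self._init_bias(hidden), requires_grad=True)
        self.wx_b = Tensor(rng.uniform(-s, s, (n_in, 4 * hidden)), requires_grad=True)
        self.wh_b = Tensor(rng.uniform(-s, s, (hidden, 4 * hidden)), requires_grad=True)
        self.b_b = Tensor(self._init_bias(hidden), requires_grad=True)

    @staticmethod
    def _init_bias(hidden):
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget gate
        return b

    def _direction(self, x, wx, wh, b, reverse):
        t_steps = x.shape[0]
        h_dim = self.hidden
        xproj = ag.add(ag.matmul(x, wx), b)
        h = Tensor(np.zeros((1, h_dim)))
        c = Tensor(np.zeros((1, h_dim)))
        order = range(t_steps - 1, -1, -1) if reverse else range(t_steps)
        outs = [None] * t_steps
        for t in order:
            gates = ag.add(xproj[t : t + 1, :], ag.matmul(h, wh))
            i = ag.sigmoid(gates[:, 0:h_dim])
            f = ag.sigmoid(gates[:, h_dim : 2 * h_dim])
            g = ag.tanh(gates[:, 2 * h_dim : 3 * h_dim])
            o = ag.sigmoid(gates[:, 3 * h_dim : 4 * h_dim])
            c = ag.add(ag.mul(f, c), ag.mul(i, g))
            h = ag.mul(o, ag.tanh(c))
            outs[t] = h
        return ag.concat(outs, axis=0)

    def forward(self, x):
        fwd = self._direction(x, self.wx_f, self.wh_f, self.b_f, reverse=False)
        bwd = self._direction(x, self.wx_b, self.wh_b, self.b_b, reverse=True)
        return ag.concat([fwd, bwd], axis=1)
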