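"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float64 ``numpy.ndarray`` together with a gradient
buffer and a closure that propagates the output gradient to its parents.
``backward()`` walks the recorded graph in reverse topological order.

The op set is deliberately small: exactly what the contact-map network needs
(broadcast arithmetic, matmul, slicing/padding, reductions, the usual
activations, and a softmax cross-entropy head).  Everything is deterministic:
given the same inputs and parameters the forward and backward passes are
bit-reproducible on one machine.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "sub",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "tanh",
    "reshape",
    "transpose",
    "getitem",
    "pad",
    "concat",
    "sum_",
    "mean",
    "scale",
    "square",
    "softmax_cross_entropy",
    "repeat2d",
    "topk_pool1d",
]


_grad_enabled = True


class no_grad:
    """Context manager disabling graph recording (inference mode).

    Inside the context no backward closures or saved activations are kept,
    so memory stays proportional to a single layer's tensors instead of the
    whole graph.
    """

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def grad_enabled():
    return _grad_enabled


class Tensor:
    """Node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        if _grad_enabled:
            self.requires_grad = bool(requires_grad) or any(
                p.requires_grad for p in parents
            )
            self._parents = parents
            self._bwd = backward
        else:
            self.requires_grad = False
            self._parents = ()
            self._bwd = None

    @property
    def _backward(self):
        return self._bwd

    @_backward.setter
    def _backward(self, fn):
        # assignments are ignored in no-grad mode so closures (and the
        # activations they capture) are dropped immediately
        self._bwd = fn if _grad_enabled else None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def _accumulate(self, g, own=False):
        """Add `g` into the gradient buffer.

        ``own=True`` promises that `g` is a freshly allocated array that no
        other node aliases, letting us adopt it without a copy.
        """
        if self.grad is None:
            if own:
                self.grad = g
            else:
                self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this tensor (default seed gradient: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # light operator sugar (used sparingly; layers call the functions below)
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a, b):
    out = Tensor(a.data + b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = bwd
    return out


def sub(a, b):
    out = Tensor(a.data - b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.data.shape))

    out._backward = bwd
    return out


def mul(a, b):
    out = Tensor(a.data * b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape), own=True)
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape), own=True)

    out._backward = bwd
    return out


def scale(a, c):
    """Multiply by a python scalar (no tensor allocated for the constant)."""
    c = float(c)
    out = Tensor(a.data * c, parents=(a,))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * c, own=True)

    out._backward = bwd
    return out


def square(a):
    return mul(a, a)


def matmul(a, b):
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T, own=True)
        if b.requires_grad:
            b._accumulate(a.data.T @ g, own=True)

    out._backward = bwd
    return out


def relu(a):
    mask = a.data > 0
    out = Tensor(a.data * mask, parents=(a,))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * mask, own=True)

    out._backward = bwd
    return out


def sigmoid(a):
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, parents=(a,))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s), own=True)

    out._backward = bwd
    return out


def tanh(a):
    t = np.tanh(a.data)
    out = Tensor(t, parents=(a,))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * (1.0 - t * t), own=True)

    out._backward = bwd
    return out


def reshape(a, shape):
    out = Tensor(a.data.reshape(shape), parents=(a,))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    out._backward = bwd
    return out


def transpose(a, axes=None):
    out = Tensor(a.data.transpose(axes), parents=(a,))
    inv = None if axes is None else np.argsort(axes)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    out._backward = bwd
    return out


def _is_basic_index(idx):
    items = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(i, (int, slice, type(None), type(Ellipsis))) for i in items)


def getitem(a, idx):
    out = Tensor(a.data[idx], parents=(a,))
    basic = _is_basic_index(idx)

    def bwd(g):
        if a.requires_grad:
            buf = np.zeros_like(a.data)
            if basic:  # basic slices never alias, so += is safe and fast
                buf[idx] += g
            else:
                np.add.at(buf, idx, g)
            a._accumulate(buf, own=True)

    out._backward = bwd
    return out


def pad(a, pad_width):
    """Zero padding; `pad_width` follows numpy's ((before, after), ...) form."""
    out = Tensor(np.pad(a.data, pad_width), parents=(a,))
    slices = tuple(
        slice(before, before + n) for (before, _), n in zip(pad_width, a.data.shape)
    )

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g[slices])

    out._backward = bwd
    return out


def concat(tensors, axis=0):
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors)
    )
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def sum_(a, axis=None, keepdims=False):
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def bwd(g):
        if a.requires_grad:
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accumulate(np.broadcast_to(gg, a.data.shape).copy(), own=True)

    out._backward = bwd
    return out


def mean(a, axis=None, keepdims=False):
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    out = Tensor(a.data.mean(axis=axis, keepdims=keepdims), parents=(a,))

    def bwd(g):
        if a.requires_grad:
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accumulate(np.broadcast_to(gg, a.data.shape) / n, own=True)

    out._backward = bwd
    return out


def repeat2d(a, factor):
    """Nearest-neighbour upsampling of the last two axes by `factor`."""
    up = np.repeat(np.repeat(a.data, factor, axis=-2), factor, axis=-1)
    out = Tensor(up, parents=(a,))
    shape = a.data.shape

    def bwd(g):
        if a.requires_grad:
            h, w = shape[-2], shape[-1]
            g4 = g.reshape(shape[:-2] + (h, factor, w, factor))
            a._accumulate(g4.sum(axis=(-3, -1)), own=True)

    out._backward = bwd
    return out


def topk_pool1d(a, patch, k):
    """Reduce each non-overlapping patch (last axis) to the mean of its k
    largest entries.  k == patch is mean pooling, k == 1 is max pooling.
    Gradient: 1/k routed to each selected entry."""
    c, length = a.data.shape
    if length % patch != 0:
        raise ValueError(f"length {length} not divisible by patch {patch}")
    k = min(int(k), int(patch))
    if k <= 0:
        raise ValueError("k must be positive")
    x = a.data.reshape(c, length // patch, patch)
    # indices of the k largest entries per patch
    idx = np.argpartition(x, patch - k, axis=-1)[..., patch - k:]
    top = np.take_along_axis(x, idx, axis=-1)
    out = Tensor(top.mean(axis=-1), parents=(a,))

    def bwd(g):
        if a.requires_grad:
            buf = np.zeros_like(x)
            np.put_along_axis(
                buf, idx, (g / k)[..., None] * np.ones((1, 1, k)), axis=-1
            )
            a._accumulate(buf.reshape(c, length), own=True)

    out._backward = bwd
    return out


def softmax_cross_entropy(logits, label):
    """Cross-entropy of a single logit vector against an integer class label."""
    z = logits.data - logits.data.max()
    logsumexp = np.log(np.exp(z).sum())
    loss = logsumexp - z[label]
    out = Tensor(loss, parents=(logits,))
    softmax = np.exp(z - logsumexp)

    def bwd(g):
        if logits.requires_grad:
            grad = softmax.copy()
            grad[label] -= 1.0
            logits._accumulate(g * grad, own=True)

    out._backward = bwd
    return out


def conv1d(x, weight, bias):
    """Same-padded stride-1 1D convolution, fused as one graph node.

    x: (c_in, L); weight: (k, c_out, c_in); bias: (c_out, 1).
    Expressed as a sum of shifted GEMMs, one per kernel tap.
    """
    k, c_out, c_in = weight.data.shape
    if k % 2 != 1:
        raise ValueError("kernel size must be odd for same padding")
    length = x.data.shape[1]
    p = (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (p, p)))
    y = np.broadcast_to(bias.data, (c_out, length)).copy()
    for t in range(k):
        y += weight.data[t] @ xp[:, t : t + length]
    out = Tensor(y, parents=(x, weight, bias))
    if not _grad_enabled:
        return out

    def bwd(g):
        if weight.requires_grad:
            dw = np.empty_like(weight.data)
            for t in range(k):
                dw[t] = g @ xp[:, t : t + length].T
            weight._accumulate(dw, own=True)
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=1, keepdims=True), own=True)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for t in range(k):
                dxp[:, t : t + length] += weight.data[t].T @ g
            x._accumulate(dxp[:, p : p + length].copy(), own=True)

    out._backward = bwd
    return out


def conv2d3x3(x, weight, bias, dilation=1):
    """Same-padded stride-1 dilated 3x3 convolution, fused as one node.

    x: (c_in, H, W); weight: (9, c_out, c_in); bias: (c_out, 1).
    """
    _, c_out, c_in = weight.data.shape
    h, w = x.data.shape[1], x.data.shape[2]
    d = int(dilation)
    xp = np.pad(x.data, ((0, 0), (d, d), (d, d)))
    flats = []
    y = np.broadcast_to(bias.data, (c_out, h * w)).copy()
    for i in range(3):
        for j in range(3):
            flat = np.ascontiguousarray(
                xp[:, i * d : i * d + h, j * d : j * d + w]
            ).reshape(c_in, h * w)
            if _grad_enabled:
                flats.append(flat)
            y += weight.data[i * 3 + j] @ flat
    out = Tensor(y.reshape(c_out, h, w), parents=(x, weight, bias))
    if not _grad_enabled:
        return out

    def bwd(g):
        gf = g.reshape(c_out, h * w)
        if weight.requires_grad:
            dw = np.empty_like(weight.data)
            for t in range(9):
                dw[t] = gf @ flats[t].T
            weight._accumulate(dw, own=True)
        if bias.requires_grad:
            bias._accumulate(gf.sum(axis=1, keepdims=True), own=True)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(3):
                for j in range(3):
                    dxp[:, i * d : i * d + h, j * d : j * d + w] += (
                        weight.data[i * 3 + j].T @ gf
                    ).reshape(c_in, h, w)
            x._accumulate(
                np.ascontiguousarray(dxp[:, d : d + h, d : d + w]), own=True
            )

    out._backward = bwd
    return out
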