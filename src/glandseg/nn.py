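"""Minimal reverse-mode automatic differentiation and layers for conv nets.

This module provides exactly the primitives the U-Net family needs:
a :class:`Tensor` with a backward tape, 2-D same-padding convolution
(stride 1, implemented as im2col + a single BLAS matmul), 2x2 max/average
pooling, 2x nearest-neighbour upsampling, batch normalization, elementwise
activations, reductions, and the Adam optimizer.  Arrays are laid out NHWC.

Everything is plain numpy, so runs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "Conv2D",
    "BatchNorm2D",
    "Module",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size 1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Array node on a backward tape.

    Only nodes with ``requires_grad`` (or with such ancestors) record a
    backward closure; constants stay out of the graph entirely.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = requires_grad
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        parents = tuple(p for p in parents if p.requires_grad)
        if parents:
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, grad):
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None):
        """Reverse-mode sweep from this node; accumulates into ``.grad``."""
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- convenience ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data ** 2))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # -- transcendental ----------------------------------------------------
    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clip values; gradient passes through only inside [lo, hi]."""
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def backward(g):
            self._accum(g.reshape(self.data.shape))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    # -- spatial ops (NHWC) ------------------------------------------------
    def maxpool2(self):
        n, h, w, c = self.data.shape
        if h % 2 or w % 2:
            raise ValueError("maxpool2 requires even spatial dims")
        win = (
            self.data.reshape(n, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h // 2, w // 2, c, 4)
        )
        idx = win.argmax(axis=-1)
        out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            gw = np.zeros((n, h // 2, w // 2, c, 4), dtype=self.data.dtype)
            np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
            gx = (
                gw.reshape(n, h // 2, w // 2, c, 2, 2)
                .transpose(0, 1, 4, 2, 5, 3)
                .reshape(n, h, w, c)
            )
            self._accum(gx)

        return Tensor._make(out_data, (self,), backward)

    def avgpool2(self):
        n, h, w, c = self.data.shape
        out_data = self.data.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

        def backward(g):
            gx = np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) * 0.25
            self._accum(gx)

        return Tensor._make(out_data, (self,), backward)

    def upsample2(self):
        """2x nearest-neighbour upsampling."""
        out_data = np.repeat(np.repeat(self.data, 2, axis=1), 2, axis=2)
        n, h, w, c = self.data.shape

        def backward(g):
            gx = g.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4))
            self._accum(gx)

        return Tensor._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * p).sum(axis=axis, keepdims=True)
            self._accum(p * (g - dot))

        return Tensor._make(p, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._make(out_data, tensors, backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _conv_same_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 same-padding correlation of NHWC `x` with (kh,kw,Cin,Cout) `w`."""
    kh, kw, cin, cout = w.shape
    if kh == 1 and kw == 1:
        return x @ w[0, 0]
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    # windows: (N, H, W, C, kh, kw) -> (N*H*W, kh*kw*C)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    n, h, wd = x.shape[0], x.shape[1], x.shape[2]
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * wd, kh * kw * cin)
    out = cols @ w.reshape(kh * kw * cin, cout)
    return out.reshape(n, h, wd, cout)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding stride-1 2-D convolution (cross-correlation), NHWC."""
    x, w = as_tensor(x), as_tensor(w)
    kh, kw, cin, cout = w.data.shape
    if x.data.shape[-1] != cin:
        raise ValueError(
            f"conv2d channel mismatch: input has {x.data.shape[-1]}, kernel expects {cin}"
        )
    out_data = _conv_same_raw(x.data, w.data)
    if b is not None:
        out_data = out_data + b.data

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        n, h, wd, _ = g.shape
        if w.requires_grad:
            if kh == 1 and kw == 1:
                dw = (
                    x.data.reshape(-1, cin).T @ g.reshape(-1, cout)
                ).reshape(1, 1, cin, cout)
            else:
                ph, pw = (kh - 1) // 2, (kw - 1) // 2
                xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
                win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
                cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * wd, kh * kw * cin)
                dw = (cols.T @ g.reshape(-1, cout)).reshape(kh, kw, cin, cout)
            w._accum(dw)
        if x.requires_grad:
            # gradient w.r.t. input = correlation with the flipped, transposed kernel
            wflip = w.data[::-1, ::-1].transpose(0, 1, 3, 2)
            x._accum(_conv_same_raw(g, wflip))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 1, 2)))

    return Tensor._make(out_data, parents, backward)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Module:
    """Base class: collects parameters from attributes and sub-modules."""

    def parameters(self) -> list[Tensor]:
        params, seen = [], set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def modules(self) -> list["Module"]:
        """All sub-modules (self included), deterministic depth-first order."""
        out = []

        def walk(obj):
            if isinstance(obj, Module):
                out.append(obj)
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return out

    def state_arrays(self) -> list[np.ndarray]:
        """Full state: parameters plus batch-norm running statistics."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm2D):
                arrays.append(m.running_mean)
                arrays.append(m.running_var)
        return arrays

    def set_state_arrays(self, arrays):
        params = self.parameters()
        n = len(params)
        for p, a in zip(params, arrays[:n], strict=False):
            p.data = a.copy()
        i = n
        for m in self.modules():
            if isinstance(m, BatchNorm2D):
                m.running_mean = arrays[i].copy()
                m.running_var = arrays[i + 1].copy()
                i += 2
        if i != len(arrays):
            raise ValueError(f"state has {len(arrays)} arrays, expected {i}")


class Conv2D(Module):
    """3x3 or 1x1 same-padding convolution with He-normal init."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float32):
        if cout <= 0:
            raise ValueError("number of filters must be positive")
        std = np.sqrt(2.0 / (ksize * ksize * cin))
        self.w = Tensor(
            (rng.standard_normal((ksize, ksize, cin, cout)) * std).astype(dtype),
            requires_grad=True,
        )
        self.b = (
            Tensor(np.zeros(cout, dtype=dtype), requires_grad=True) if bias else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)


class BatchNorm2D(Module):
    """Batch normalization over (N, H, W) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        gamma, beta, eps = self.gamma, self.beta, self.eps
        if training:
            mu = x.data.mean(axis=(0, 1, 2))
            var = x.data.var(axis=(0, 1, 2))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            ).astype(self.running_mean.dtype)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(self.running_var.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu) * inv_std
        out_data = gamma.data * xhat + beta.data
        m = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]

        def backward(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 1, 2)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 1, 2)))
            if x.requires_grad:
                if training:
                    gmean = g.mean(axis=(0, 1, 2))
                    gxhat_mean = (g * xhat).sum(axis=(0, 1, 2)) / m
                    dx = gamma.data * inv_std * (g - gmean - xhat * gxhat_mean)
                else:
                    dx = g * (gamma.data * inv_std)
                x._accum(dx)

        return Tensor._make(out_data, (x, gamma, beta), backward)


class Adam:
    """Adam optimizer (Kingma & Ba) over a parameter list; lr is mutable."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
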