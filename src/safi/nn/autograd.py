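"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: every ``Tensor`` records its parents
and a closure that accumulates gradients into them.  Convolutions are lowered
to BLAS matmuls via im2col; depthwise and 1x1 convolutions take cheaper
dedicated paths.  Only the operations required by the detection models in
this package are implemented.
"""
from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "stack",
    "where",
    "maximum",
    "minimum",
    "bce_with_logits",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=dtype) if dtype is not None else np.asarray(data)
        if self.data.dtype == np.float64 and dtype is None and not requires_grad:
            pass  # keep caller-chosen precision
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = _grad_enabled and any(p.requires_grad for p in parents)
        t = Tensor(data)
        if req:
            t.requires_grad = True
            t._parents = tuple(parents)
            t._backward = backward
        return t

    # -- basic protocol -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    def item(self):
        return self.data.item()

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def astype(self, dtype) -> "Tensor":
        out_data = self.data.astype(dtype)

        def backward(grad, self=self):
            _accum(self, grad.astype(self.data.dtype))

        return Tensor._make(out_data, (self,), backward)

    # -- autograd driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=self.data.dtype)

        topo: list[Tensor] = []
        visited = set()
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

        self.grad = grad if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free closures / cached activations
                node._parents = ()

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, self.dtype)
        out = self.data + other.data

        def backward(grad, a=self, b=other):
            _accum(a, _unbroadcast(grad, a.shape))
            _accum(b, _unbroadcast(grad, b.shape))

        return Tensor._make(out, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad, a=self):
            _accum(a, -grad)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.dtype)
        out = self.data * other.data

        def backward(grad, a=self, b=other):
            _accum(a, _unbroadcast(grad * b.data, a.shape))
            _accum(b, _unbroadcast(grad * a.data, b.shape))

        return Tensor._make(out, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other, self.dtype)
        out = self.data / other.data

        def backward(grad, a=self, b=other):
            _accum(a, _unbroadcast(grad / b.data, a.shape))
            _accum(b, _unbroadcast(-grad * a.data / (b.data * b.data), b.shape))

        return Tensor._make(out, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other, self.dtype) / self

    def __pow__(self, p: float):
        out = self.data ** p

        def backward(grad, a=self, p=p):
            _accum(a, grad * p * a.data ** (p - 1))

        return Tensor._make(out, (self,), backward)

    def __getitem__(self, idx):
        out = self.data[idx]

        def backward(grad, a=self, idx=idx):
            g = np.zeros_like(a.data)
            np.add.at(g, idx, grad)
            _accum(a, g)

        return Tensor._make(out, (self,), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        out = np.exp(self.data)

        def backward(grad, a=self, out=out):
            _accum(a, grad * out)

        return Tensor._make(out, (self,), backward)

    def log(self):
        out = np.log(self.data)

        def backward(grad, a=self):
            _accum(a, grad / a.data)

        return Tensor._make(out, (self,), backward)

    def sqrt(self):
        out = np.sqrt(self.data)

        def backward(grad, a=self, out=out):
            _accum(a, grad * 0.5 / out)

        return Tensor._make(out, (self,), backward)

    def abs(self):
        out = np.abs(self.data)

        def backward(grad, a=self):
            _accum(a, grad * np.sign(a.data))

        return Tensor._make(out, (self,), backward)

    def sigmoid(self):
        out = _sigmoid(self.data)

        def backward(grad, a=self, out=out):
            _accum(a, grad * out * (1.0 - out))

        return Tensor._make(out, (self,), backward)

    def silu(self):
        s = _sigmoid(self.data)
        out = self.data * s

        def backward(grad, a=self, s=s):
            _accum(a, grad * (s * (1.0 + a.data * (1.0 - s))))

        return Tensor._make(out, (self,), backward)

    def relu(self):
        out = np.maximum(self.data, 0)

        def backward(grad, a=self):
            _accum(a, grad * (a.data > 0))

        return Tensor._make(out, (self,), backward)

    def relu6(self):
        out = np.clip(self.data, 0.0, 6.0)

        def backward(grad, a=self):
            _accum(a, grad * ((a.data > 0) & (a.data < 6)))

        return Tensor._make(out, (self,), backward)

    def clamp(self, lo=None, hi=None):
        out = np.clip(self.data, lo, hi)

        def backward(grad, a=self, lo=lo, hi=hi):
            mask = np.ones_like(a.data, dtype=bool)
            if lo is not None:
                mask &= a.data >= lo
            if hi is not None:
                mask &= a.data <= hi
            _accum(a, grad * mask)

        return Tensor._make(out, (self,), backward)

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad, a=self, axis=axis, keepdims=keepdims):
            if axis is None:
                g = np.broadcast_to(grad, a.shape)
            else:
                if not keepdims:
                    grad = np.expand_dims(grad, axis)
                g = np.broadcast_to(grad, a.shape)
            _accum(a, g.astype(a.data.dtype, copy=False))

        return Tensor._make(out, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self.data.reshape(shape)

        def backward(grad, a=self):
            _accum(a, grad.reshape(a.shape))

        return Tensor._make(out, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(grad, a=self, inv=tuple(inv)):
            _accum(a, grad.transpose(inv))

        return Tensor._make(out, (self,), backward)

    def matmul(self, other: "Tensor"):
        other = _as_tensor(other, self.dtype)
        out = self.data @ other.data

        def backward(grad, a=self, b=other):
            ga = grad @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ grad
            _accum(a, _unbroadcast(ga, a.shape))
            _accum(b, _unbroadcast(gb, b.shape))

        return Tensor._make(out, (self, other), backward)

    __matmul__ = matmul


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data, dtype=np.float32):
        super().__init__(np.asarray(data, dtype=dtype), requires_grad=True)


def _as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _accum(t: Tensor, grad: np.ndarray):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(grad, dtype=t.data.dtype, copy=True)
    else:
        t.grad += grad


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad, tensors=tensors, offsets=offsets, axis=axis):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * grad.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, grad[tuple(sl)])

    return Tensor._make(out, tuple(tensors), backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)

    def backward(grad, tensors=tensors, axis=axis):
        for i, t in enumerate(tensors):
            _accum(t, np.take(grad, i, axis=axis))

    return Tensor._make(out, tuple(tensors), backward)


def maximum(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = np.maximum(a.data, b.data)

    def backward(grad, a=a, b=b):
        mask = a.data >= b.data
        _accum(a, _unbroadcast(grad * mask, a.shape))
        _accum(b, _unbroadcast(grad * ~mask, b.shape))

    return Tensor._make(out, (a, b), backward)


def minimum(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = np.minimum(a.data, b.data)

    def backward(grad, a=a, b=b):
        mask = a.data <= b.data
        _accum(a, _unbroadcast(grad * mask, a.shape))
        _accum(b, _unbroadcast(grad * ~mask, b.shape))

    return Tensor._make(out, (a, b), backward)


def where(cond: np.ndarray, a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    cond = np.asarray(cond, dtype=bool)
    out = np.where(cond, a.data, b.data)

    def backward(grad, a=a, b=b, cond=cond):
        _accum(a, _unbroadcast(grad * cond, a.shape))
        _accum(b, _unbroadcast(grad * ~cond, b.shape))

    return Tensor._make(out, (a, b), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy on logits (numerically stable)."""
    x = logits.data
    t = np.asarray(targets, dtype=x.dtype)
    out = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))

    def backward(grad, a=logits, t=t):
        _accum(a, grad * (_sigmoid(a.data) - t))

    return Tensor._make(out, (logits,), backward)


# ---------------------------------------------------------------------------
# convolution & friends
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, kh * kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i * kw + j] = x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c, kh * kw, ho * wo), ho, wo


def _col2im(dcols: np.ndarray, x_shape, kh, kw, stride, pad, ho, wo):
    n, c, h, w = x_shape
    dcols = dcols.reshape(n, c, kh * kw, ho, wo)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[:, :, i * kw + j]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D convolution.  weight: (Cout, Cin/groups, kh, kw)."""
    n, cin, h, w = x.shape
    cout, cin_g, kh, kw = weight.shape
    if cin_g * groups != cin:
        raise ValueError(
            f"conv2d channel mismatch: input has {cin} channels, "
            f"weight expects {cin_g * groups} (groups={groups})"
        )
    if groups == cin and cin_g == 1 and cout == cin:
        out = _dwconv_forward(x, weight, bias, stride, padding)
        return out
    if kh == 1 and kw == 1 and padding == 0:
        return _conv1x1(x, weight, bias, stride, groups)
    return _conv_im2col(x, weight, bias, stride, padding, groups)


def _add_bias(out_data, bias):
    if bias is not None:
        out_data += bias.data.reshape(1, -1, 1, 1)
    return out_data


def _bias_parents(parents, bias):
    return parents + (bias,) if bias is not None else parents


def _conv_im2col(x, weight, bias, stride, padding, groups):
    n, cin, h, w = x.shape
    cout, cin_g, kh, kw = weight.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    k = cin_g * kh * kw
    cols_g = cols.reshape(n, groups, k, ho * wo)
    w_r = weight.data.reshape(groups, cout // groups, k)
    out = np.matmul(w_r, cols_g)  # (n, g, cout_g, L)
    out = out.reshape(n, cout, ho, wo)
    out = _add_bias(out, bias)

    def backward(grad, x=x, weight=weight, bias=bias, stride=stride,
                 padding=padding, groups=groups, ho=ho, wo=wo):
        n, cin, h, w = x.shape
        cout, cin_g, kh, kw = weight.shape
        k = cin_g * kh * kw
        g_r = grad.reshape(n, groups, cout // groups, ho * wo)
        # recompute cols (trades FLOPs for memory)
        cols, _, _ = _im2col(x.data, kh, kw, stride, padding)
        cols_g = cols.reshape(n, groups, k, ho * wo)
        dw = np.matmul(g_r, cols_g.swapaxes(-1, -2)).sum(axis=0)
        _accum(weight, dw.reshape(weight.shape))
        if bias is not None:
            _accum(bias, grad.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            w_r = weight.data.reshape(groups, cout // groups, k)
            dcols = np.matmul(w_r.swapaxes(-1, -2), g_r)  # (n, g, k, L)
            dx = _col2im(dcols.reshape(n, cin * kh * kw, ho * wo), x.shape,
                         kh, kw, stride, padding, ho, wo)
            _accum(x, dx)

    return Tensor._make(out, _bias_parents((x, weight), bias), backward)


def _conv1x1(x, weight, bias, stride, groups):
    n, cin, h, w = x.shape
    cout = weight.shape[0]
    xd = x.data[:, :, ::stride, ::stride] if stride > 1 else x.data
    ho, wo = xd.shape[2], xd.shape[3]
    xg = xd.reshape(n, groups, cin // groups, ho * wo)
    w_r = weight.data.reshape(groups, cout // groups, cin // groups)
    out = np.matmul(w_r, xg).reshape(n, cout, ho, wo)
    out = _add_bias(out, bias)

    def backward(grad, x=x, weight=weight, bias=bias, stride=stride,
                 groups=groups, ho=ho, wo=wo):
        n, cin, h, w = x.shape
        cout = weight.shape[0]
        xd = x.data[:, :, ::stride, ::stride] if stride > 1 else x.data
        xg = xd.reshape(n, groups, cin // groups, ho * wo)
        g_r = grad.reshape(n, groups, cout // groups, ho * wo)
        dw = np.matmul(g_r, xg.swapaxes(-1, -2)).sum(axis=0)
        _accum(weight, dw.reshape(weight.shape))
        if bias is not None:
            _accum(bias, grad.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            w_r = weight.data.reshape(groups, cout // groups, cin // groups)
            dxg = np.matmul(w_r.swapaxes(-1, -2), g_r).reshape(n, cin, ho, wo)
            if stride > 1:
                dx = np.zeros_like(x.data)
                dx[:, :, ::stride, ::stride] = dxg
            else:
                dx = dxg
            _accum(x, dx)

    return Tensor._make(out, _bias_parents((x, weight), bias), backward)


def _dwconv_forward(x, weight, bias, stride, padding):
    """Depthwise convolution via k*k shifted fused multiply-adds."""
    n, c, h, w = x.shape
    _, _, kh, kw = weight.shape
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (w + 2 * padding - kw) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    out = np.zeros((n, c, ho, wo), dtype=x.data.dtype)
    wd = weight.data  # (c, 1, kh, kw)
    for i in range(kh):
        for j in range(kw):
            out += wd[:, 0, i, j].reshape(1, c, 1, 1) * xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    out = _add_bias(out, bias)

    def backward(grad, x=x, weight=weight, bias=bias, stride=stride,
                 padding=padding, ho=ho, wo=wo):
        n, c, h, w = x.shape
        _, _, kh, kw = weight.shape
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
        dw = np.empty_like(weight.data)
        need_dx = x.requires_grad or x._parents
        dxp = np.zeros_like(xp) if need_dx else None
        wd = weight.data
        for i in range(kh):
            for j in range(kw):
                sl = np.s_[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
                dw[:, 0, i, j] = np.einsum("nchw,nchw->c", grad, xp[sl])
                if need_dx:
                    dxp[sl] += wd[:, 0, i, j].reshape(1, c, 1, 1) * grad
        _accum(weight, dw)
        if bias is not None:
            _accum(bias, grad.sum(axis=(0, 2, 3)))
        if need_dx:
            dx = dxp[:, :, padding : padding + h, padding : padding + w] if padding else dxp
            _accum(x, dx)

    return Tensor._make(out, _bias_parents((x, weight), bias), backward)


def max_pool2d(x: Tensor, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    n, c, h, w = x.shape
    ho = (h + 2 * padding - kernel) // stride + 1
    wo = (w + 2 * padding - kernel) // stride + 1
    if padding:
        xp = np.full((n, c, h + 2 * padding, w + 2 * padding), -np.inf, dtype=x.data.dtype)
        xp[:, :, padding : padding + h, padding : padding + w] = x.data
    else:
        xp = x.data
    out = np.full((n, c, ho, wo), -np.inf, dtype=x.data.dtype)
    arg = np.zeros((n, c, ho, wo), dtype=np.int16)
    for idx in range(kernel * kernel):
        i, j = divmod(idx, kernel)
        cand = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
        better = cand > out
        out[better] = cand[better]
        arg[better] = idx

    def backward(grad, x=x, arg=arg, kernel=kernel, stride=stride,
                 padding=padding, ho=ho, wo=wo):
        n, c, h, w = x.shape
        dxp = np.zeros((n, c, h + 2 * padding, w + 2 * padding), dtype=grad.dtype)
        for idx in range(kernel * kernel):
            i, j = divmod(idx, kernel)
            mask = arg == idx
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += grad * mask
        dx = dxp[:, :, padding : padding + h, padding : padding + w] if padding else dxp
        _accum(x, dx)

    return Tensor._make(out, (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(grad, x=x):
        n, c, h2, w2 = grad.shape
        g = grad.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        _accum(x, g)

    return Tensor._make(out, (x,), backward)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float):
    """Fused training-mode batch norm over (N, H, W) per channel.

    Returns (out, batch_mean, batch_var) with mean/var as plain arrays.
    """
    xd = x.data
    mu = xd.mean(axis=(0, 2, 3), keepdims=True)
    var = xd.var(axis=(0, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * inv
    g = gamma.data.reshape(1, -1, 1, 1).astype(xd.dtype)
    out = g * xhat + beta.data.reshape(1, -1, 1, 1).astype(xd.dtype)

    def backward(grad, x=x, gamma=gamma, beta=beta, xhat=xhat, inv=inv, g=g):
        _accum(gamma, (grad * xhat).sum(axis=(0, 2, 3)).astype(gamma.data.dtype))
        _accum(beta, grad.sum(axis=(0, 2, 3)).astype(beta.data.dtype))
        if x.requires_grad or x._parents:
            dxhat = grad * g
            m1 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
            m2 = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
            _accum(x, inv * (dxhat - m1 - xhat * m2))

    return Tensor._make(out, (x, gamma, beta), backward), mu.ravel(), var.ravel()


def batch_norm_eval(x: Tensor, gamma: Tensor, beta: Tensor,
                    mean: np.ndarray, var: np.ndarray, eps: float) -> Tensor:
    inv = (1.0 / np.sqrt(var + eps)).reshape(1, -1, 1, 1).astype(x.dtype)
    g = gamma.data.reshape(1, -1, 1, 1).astype(x.dtype)
    xhat = (x.data - mean.reshape(1, -1, 1, 1)) * inv
    out = g * xhat + beta.data.reshape(1, -1, 1, 1).astype(x.dtype)

    def backward(grad, x=x, gamma=gamma, beta=beta, xhat=xhat, inv=inv, g=g):
        _accum(gamma, (grad * xhat).sum(axis=(0, 2, 3)).astype(gamma.data.dtype))
        _accum(beta, grad.sum(axis=(0, 2, 3)).astype(beta.data.dtype))
        if x.requires_grad or x._parents:
            _accum(x, grad * (g * inv))

    return Tensor._make(out, (x, gamma, beta), backward)


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int, eps: float) -> Tensor:
    n, c, h, w = x.shape
    xg = x.data.reshape(n, groups, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(n, c, h, w)
    g = gamma.data.reshape(1, -1, 1, 1).astype(x.dtype)
    out = g * xhat + beta.data.reshape(1, -1, 1, 1).astype(x.dtype)

    def backward(grad, x=x, gamma=gamma, beta=beta, xhat=xhat, inv=inv, g=g,
                 groups=groups):
        n, c, h, w = x.shape
        _accum(gamma, (grad * xhat).sum(axis=(0, 2, 3)).astype(gamma.data.dtype))
        _accum(beta, grad.sum(axis=(0, 2, 3)).astype(beta.data.dtype))
        if x.requires_grad or x._parents:
            dxhat = (grad * g).reshape(n, groups, -1)
            xh = xhat.reshape(n, groups, -1)
            m1 = dxhat.mean(axis=2, keepdims=True)
            m2 = (dxhat * xh).mean(axis=2, keepdims=True)
            dx = inv * (dxhat - m1 - xh * m2)
            _accum(x, dx.reshape(n, c, h, w))

    return Tensor._make(out, (x, gamma, beta), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(grad, x=x, out=out, axis=axis):
        dot = (grad * out).sum(axis=axis, keepdims=True)
        _accum(x, out * (grad - dot))

    return Tensor._make(out, (x,), backward)
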