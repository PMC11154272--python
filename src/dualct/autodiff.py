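"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operator set the reconstruction networks need:
broadcast arithmetic, matmul, elementwise nonlinearities, reductions,
slicing/reshape/concat, strided/grouped 2-D convolution, bilinear 2x
upsampling and softmax.  Gradients are accumulated by topological
traversal from the output node; correctness is pinned down by the
finite-difference tests in the test suite.
"""

from __future__ import annotations

import numpy as np

# global switch: with grad_enabled False no graph is built (inference mode)
grad_enabled = True


class no_grad:
    def __enter__(self):
        global grad_enabled
        self._prev = grad_enabled
        grad_enabled = False
        return self

    def __exit__(self, *exc):
        global grad_enabled
        grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
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
    """An array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) and grad_enabled
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self):
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd engine ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and not t._parents:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is not None:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if pg is None or not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _node(self.data + other.data, (self, other))
        if out._parents:
            out._backward = lambda g: (
                _unbroadcast(g, self.shape),
                _unbroadcast(g, other.shape),
            )
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        if out._parents:
            out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _node(self.data * other.data, (self, other))
        if out._parents:
            out._backward = lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = _node(self.data ** p, (self,))
        if out._parents:
            out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _node(self.data @ other.data, (self, other))
        if out._parents:
            out._backward = lambda g: (g @ other.data.T, self.data.T @ g)
        return out

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        if out._parents:
            out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = _node(self.data.transpose(axes), (self,))
        if out._parents:
            out._backward = lambda g: (g.transpose(inv),)
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))
        if out._parents:
            def bwd(g):
                gx = np.zeros_like(self.data)
                gx[idx] += g
                return (gx,)
            out._backward = bwd
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            def bwd(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                return (np.broadcast_to(g, self.shape).copy(),)
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = _node(y, (self,))
        if out._parents:
            out._backward = lambda g: (g * y,)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        if out._parents:
            out._backward = lambda g: (g / self.data,)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = _node(y, (self,))
        if out._parents:
            out._backward = lambda g: (g * (1.0 - y * y),)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(y, (self,))
        if out._parents:
            out._backward = lambda g: (g * y * (1.0 - y),)
        return out

    def relu(self):
        y = np.maximum(self.data, 0.0)
        out = _node(y, (self,))
        if out._parents:
            mask = self.data > 0
            out._backward = lambda g: (g * mask,)
        return out

    def abs(self):
        out = _node(np.abs(self.data), (self,))
        if out._parents:
            s = np.sign(self.data)
            out._backward = lambda g: (g * s,)
        return out

    def sqrt(self):
        return self ** 0.5


class Parameter(Tensor):
    """A leaf tensor optimized during training."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)
        self.requires_grad = True  # parameters track grads even in no_grad scope


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _node(data: np.ndarray, parents) -> Tensor:
    out = Tensor(data)
    if grad_enabled:
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = parents
            out.requires_grad = True
    return out


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concatenate(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._parents:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def softmax(x: Tensor, axis=-1):
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = _node(y, (x,))
    if out._parents:
        out._backward = lambda g: (y * (g - (g * y).sum(axis=axis, keepdims=True)),)
    return out


def conv2d(x: Tensor, weight: Tensor, bias=None, stride=1, padding=0, groups=1):
    """2-D convolution (cross-correlation) on a (C, H, W) feature map.

    weight: (C_out, C_in // groups, kh, kw); bias: (C_out,) or None.
    """
    x = as_tensor(x)
    weight = as_tensor(weight)
    cin, H, W = x.shape
    cout, cg, kh, kw = weight.shape
    if cg * groups != cin:
        raise ValueError(
            f"channel mismatch: input {cin}, weight expects {cg * groups}"
        )
    s, p = int(stride), int(padding)
    if groups == cin and cg == 1 and cout == cin:
        return _depthwise_conv2d(x, weight, bias, s, p)
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p))) if p else x.data
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    cog = cout // groups
    if groups == 1:
        # im2col once; the column matrix is reused by the backward pass
        win = np.lib.stride_tricks.sliding_window_view(
            xp, (kh, kw), axis=(1, 2))[:, ::s, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 3, 4, 1, 2)).reshape(
            cin * kh * kw, Ho * Wo)
        out = (weight.data.reshape(cout, -1) @ cols).reshape(cout, Ho, Wo)
    else:
        win = np.lib.stride_tricks.sliding_window_view(
            xp, (kh, kw), axis=(1, 2))[:, ::s, ::s]
        cols = None
        out = np.empty((cout, Ho, Wo), dtype=x.dtype)
        for gi in range(groups):
            wg = weight.data[gi * cog:(gi + 1) * cog]
            vg = win[gi * cg:(gi + 1) * cg]
            out[gi * cog:(gi + 1) * cog] = np.tensordot(
                wg, vg, axes=([1, 2, 3], [0, 3, 4]))
    if bias is not None:
        out = out + as_tensor(bias).data[:, None, None]
    parents = (x, weight) + ((bias,) if bias is not None else ())
    node = _node(out, parents)
    if node._parents:
        def bwd(g):
            dxp = np.zeros_like(xp)
            if groups == 1:
                gm = g.reshape(cout, Ho * Wo)
                dw = (gm @ cols.T).reshape(weight.shape)
                for i in range(kh):
                    for j in range(kw):
                        contrib = np.tensordot(weight.data[:, :, i, j], g,
                                               axes=([0], [0]))
                        dxp[:, i:i + s * Ho:s, j:j + s * Wo:s] += contrib
            else:
                dw = np.empty_like(weight.data)
                for gi in range(groups):
                    go = g[gi * cog:(gi + 1) * cog]
                    vg = win[gi * cg:(gi + 1) * cg]
                    dw[gi * cog:(gi + 1) * cog] = np.tensordot(
                        go, vg, axes=([1, 2], [1, 2]))
                    wg = weight.data[gi * cog:(gi + 1) * cog]
                    for i in range(kh):
                        for j in range(kw):
                            contrib = np.tensordot(wg[:, :, i, j], go,
                                                   axes=([0], [0]))
                            dxp[gi * cg:(gi + 1) * cg,
                                i:i + s * Ho:s, j:j + s * Wo:s] += contrib
            dx = dxp[:, p:p + H, p:p + W] if p else dxp
            grads = [dx, dw]
            if bias is not None:
                grads.append(g.sum(axis=(1, 2)))
            return tuple(grads)
        node._backward = bwd
    return node


def _depthwise_conv2d(x: Tensor, weight: Tensor, bias, s: int, p: int):
    """Depthwise conv via kernel-tap accumulation (no per-channel loop)."""
    cin, H, W = x.shape
    _, _, kh, kw = weight.shape
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p))) if p else x.data
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    out = np.zeros((cin, Ho, Wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            out += weight.data[:, 0, i, j][:, None, None] * \
                xp[:, i:i + s * Ho:s, j:j + s * Wo:s]
    if bias is not None:
        out += as_tensor(bias).data[:, None, None]
    parents = (x, weight) + ((bias,) if bias is not None else ())
    node = _node(out, parents)
    if node._parents:
        def bwd(g):
            dw = np.empty_like(weight.data)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    view = xp[:, i:i + s * Ho:s, j:j + s * Wo:s]
                    dw[:, 0, i, j] = (g * view).sum(axis=(1, 2))
                    dxp[:, i:i + s * Ho:s, j:j + s * Wo:s] += \
                        weight.data[:, 0, i, j][:, None, None] * g
            dx = dxp[:, p:p + H, p:p + W] if p else dxp
            grads = [dx, dw]
            if bias is not None:
                grads.append(g.sum(axis=(1, 2)))
            return tuple(grads)
        node._backward = bwd
    return node


def _linear_taps(n_out: int, n_in: int):
    """Index/weight taps for align_corners=False linear resampling."""
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    i0f = np.floor(src)
    w1 = src - i0f
    i0 = np.clip(i0f, 0, n_in - 1).astype(np.intp)
    i1 = np.clip(i0f + 1, 0, n_in - 1).astype(np.intp)
    return i0, i1, (1.0 - w1), w1


def _interp_axis(x: Tensor, n_out: int, axis: int):
    n_in = x.shape[axis]
    i0, i1, w0, w1 = _linear_taps(n_out, n_in)
    shape = [1] * x.ndim
    shape[axis] = n_out
    w0b = w0.reshape(shape)
    w1b = w1.reshape(shape)
    y = np.take(x.data, i0, axis=axis) * w0b + np.take(x.data, i1, axis=axis) * w1b
    out = _node(y.astype(x.dtype, copy=False), (x,))
    if out._parents:
        def bwd(g):
            gx = np.zeros_like(x.data)
            gm = np.moveaxis(gx, axis, 0)
            gg = np.moveaxis(g, axis, 0)
            w0c = w0.reshape((n_out,) + (1,) * (x.ndim - 1))
            w1c = w1.reshape((n_out,) + (1,) * (x.ndim - 1))
            np.add.at(gm, i0, gg * w0c)
            np.add.at(gm, i1, gg * w1c)
            return (gx,)
        out._backward = bwd
    return out


def upsample2_bilinear(x: Tensor):
    """Bilinear 2x spatial upsampling of a (C, H, W) feature map."""
    x = as_tensor(x)
    c, h, w = x.shape
    return _interp_axis(_interp_axis(x, 2 * h, axis=1), 2 * w, axis=2)


def global_avg_pool(x: Tensor):
    """Spatial mean of a (C, H, W) map -> (C, 1, 1)."""
    return x.mean(axis=(1, 2), keepdims=True)
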