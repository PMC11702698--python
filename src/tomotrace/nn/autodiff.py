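"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is deliberately small: dense float64 tensors, a static tape built on the
fly, and exactly the primitives the edge transformer and the segmentation CNN
need (broadcast arithmetic, matmul, softmax, conv2d, pooling, resampling).
Gradients accumulate into ``Tensor.grad`` after :meth:`Tensor.backward`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))
        return self._make(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        def backward(g, a=self, n=exponent):
            if a.requires_grad:
                a._accum(g * n * a.data ** (n - 1))
        return self._make(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data
        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))
        return self._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * y)
        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)
        return self._make(np.log(self.data), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * y * (1.0 - y))
        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)
        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * (1.0 - y * y))
        return self._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.01):
        mask = np.where(self.data > 0, 1.0, slope)
        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)
        return self._make(self.data * mask, (self,), backward)

    def softplus(self):
        # log(1 + e^x), computed stably; d/dx = sigmoid(x)
        out_data = np.logaddexp(0.0, self.data)
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / (1.0 + np.exp(-a.data)))
        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        def backward(g, a=self, y=y, axis=axis):
            if a.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                a._accum(y * (g - dot))
        return self._make(y, (self,), backward)

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.data.shape).copy())
        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        def backward(g, a=self, old=old):
            if a.requires_grad:
                a._accum(g.reshape(old))
        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        def backward(g, a=self, inv=tuple(inv)):
            if a.requires_grad:
                a._accum(g.transpose(inv))
        return self._make(self.data.transpose(axes), (self,), backward)

    @staticmethod
    def concat(tensors, axis: int = 0):
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        def backward(g, ts=tensors, sizes=sizes, axis=axis):
            offs = np.cumsum([0] + sizes)
            for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * g.ndim
                    idx[axis] = slice(lo, hi)
                    t._accum(g[tuple(idx)])
        out = Tensor(out_data)
        out.requires_grad = any(t.requires_grad for t in tensors)
        if out.requires_grad:
            out._parents = tuple(tensors)
            out._backward = backward
        return out

    # -- spatial primitives (NCHW) -------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None):
        """Same-padding 3x3 (or any odd k) convolution, stride 1.

        self: (N, C, H, W); weight: (O, C, kh, kw); bias: (O,).
        Implemented as a sum of shifted 1x1 convolutions.
        """
        x = self.data
        w = weight.data
        kh, kw = w.shape[2], w.shape[3]
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        N, C, H, W = x.shape
        O = w.shape[0]
        out_data = np.zeros((N, O, H, W))
        for di in range(kh):
            for dj in range(kw):
                patch = xp[:, :, di:di + H, dj:dj + W]
                out_data += np.einsum("nchw,oc->nohw", patch, w[:, :, di, dj], optimize=True)
        if bias is not None:
            out_data += bias.data.reshape(1, O, 1, 1)
        parents = (self, weight) if bias is None else (self, weight, bias)

        def backward(g, a=self, wt=weight, b=bias, xp=xp):
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if wt.requires_grad:
                gw = np.empty_like(wt.data)
                for di in range(kh):
                    for dj in range(kw):
                        patch = xp[:, :, di:di + H, dj:dj + W]
                        gw[:, :, di, dj] = np.einsum("nohw,nchw->oc", g, patch, optimize=True)
                wt._accum(gw)
            if a.requires_grad:
                gxp = np.zeros_like(xp)
                for di in range(kh):
                    for dj in range(kw):
                        gxp[:, :, di:di + H, dj:dj + W] += np.einsum(
                            "nohw,oc->nchw", g, wt.data[:, :, di, dj], optimize=True)
                a._accum(gxp[:, :, ph:ph + H, pw:pw + W])
        return self._make(out_data, parents, backward)

    def max_pool2d(self):
        """2x2 max pooling, stride 2; trailing odd row/col dropped."""
        x = self.data
        N, C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        v = x[:, :, :H2 * 2, :W2 * 2].reshape(N, C, H2, 2, W2, 2)
        out_data = v.max(axis=(3, 5))
        mask = (v == out_data[:, :, :, None, :, None])
        # break ties: keep only the first maximum in each 2x2 window
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H2, W2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        mask = (flat & first).reshape(N, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        def backward(g, a=self, mask=mask):
            if a.requires_grad:
                gx = np.zeros_like(a.data)
                gv = mask * g[:, :, :, None, :, None]
                gx[:, :, :H2 * 2, :W2 * 2] = gv.reshape(N, C, H2 * 2, W2 * 2)
                a._accum(gx)
        return self._make(out_data, (self,), backward)

    def upsample2x(self):
        """Nearest-neighbour 2x upsampling on the two trailing axes."""
        out_data = self.data.repeat(2, axis=-2).repeat(2, axis=-1)
        def backward(g, a=self):
            if a.requires_grad:
                N, C, H, W = a.data.shape
                gv = g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5))
                a._accum(gv)
        return self._make(out_data, (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()
        stack = [(self, False)]
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._parents = ()
                node._backward = None


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
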