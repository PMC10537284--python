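"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in this package is trained with first-order methods, so every
layer is expressed in terms of a small set of differentiable array
operations collected here.  A :class:`Tensor` wraps an ``ndarray`` and
records the operations that produced it; :meth:`Tensor.backward` walks the
recorded graph in reverse topological order and accumulates gradients into
every tensor created with ``requires_grad=True``.

Only the operations the network actually needs are implemented: broadcasted
arithmetic, matmul, exp/log/sqrt/erf/abs, reductions, shape manipulation,
concatenation, fancy indexing, and a same-padding dilated 2-D convolution.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

__all__ = ["Tensor", "concatenate", "conv2d", "custom_op"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus the tape entry needed for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- graph construction ------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        if not req:
            return Tensor(data)
        return Tensor(data, requires_grad=True, parents=parents, backward=backward)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self ** (-1.0)

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")

        def bwd(g):
            return (g * p * self.data ** (p - 1.0),)

        return self._make(self.data**p, (self,), bwd)

    def __matmul__(self, other):
        other = self._lift(other)

        def bwd(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                return (g * b, g * a)
            if a.ndim == 1:  # (k,) @ (..,k,n)
                ga = (g[..., None, :] @ np.swapaxes(b, -1, -2)).reshape(b.shape[:-2] + a.shape)
                ga = _unbroadcast(ga, a.shape)
                gb = a[:, None] * g[..., None, :]
                return (ga, _unbroadcast(gb, b.shape))
            if b.ndim == 1:  # (..,m,k) @ (k,)
                ga = g[..., :, None] * b[None, :]
                gb = np.swapaxes(a, -1, -2) @ g[..., :, None]
                return (_unbroadcast(ga, a.shape), _unbroadcast(gb.reshape(a.shape[:-2] + b.shape), b.shape))
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return self._make(self.data @ other.data, (self, other), bwd)

    # -- elementwise transcendental -----------------------------------------
    def exp(self):
        out = np.exp(self.data)

        def bwd(g):
            return (g * out,)

        return self._make(out, (self,), bwd)

    def log(self):
        def bwd(g):
            return (g / self.data,)

        return self._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        return self**0.5

    def erf(self):
        def bwd(g):
            return (g * (2.0 / np.sqrt(np.pi)) * np.exp(-self.data**2),)

        return self._make(_sp.erf(self.data), (self,), bwd)

    def abs(self):
        # subgradient at 0 taken as 0, the usual l1 convention
        def bwd(g):
            return (g * np.sign(self.data),)

        return self._make(np.abs(self.data), (self,), bwd)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g):
            return (g.reshape(self.shape),)

        return self._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            return (g.transpose(inv),)

        return self._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g):
            out = np.zeros(self.shape)
            np.add.at(out, idx, g)
            return (out,)

        return self._make(self.data[idx], (self,), bwd)

    # -- backward pass ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
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

        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pg in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad or pg is None:
                    continue
                pg = np.asarray(pg, dtype=parent.data.dtype)
                if parent.grad is None:
                    parent.grad = pg
                else:
                    parent.grad = parent.grad + pg

    def zero_grad(self):
        self.grad = None


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        grads = []
        for i in range(len(tensors)):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            grads.append(g[tuple(sl)])
        return tuple(grads)

    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    if not req:
        return Tensor(data)
    return Tensor(data, requires_grad=True, parents=tuple(tensors), backward=bwd)


def custom_op(inputs, forward_value: np.ndarray, backward_fn) -> Tensor:
    """Register a hand-written op: ``backward_fn(grad) -> tuple of input grads``."""
    inputs = tuple(Tensor._lift(t) for t in inputs)
    req = any(t.requires_grad for t in inputs)
    if not req:
        return Tensor(forward_value)
    return Tensor(forward_value, requires_grad=True, parents=inputs, backward=backward_fn)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Same-padding 2-D convolution (cross-correlation).

    x: (N, C, H, W); w: (O, C, k, k) with k odd; b: (O,) or None.
    Output spatial size equals input size for every odd kernel and dilation.
    """
    x = Tensor._lift(x)
    w = Tensor._lift(w)
    n, c, h, wd = x.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d requires odd kernel sizes")
    ph = dilation * (kh - 1) // 2
    pw = dilation * (kw - 1) // 2

    if ph or pw:
        xp = np.zeros((n, c, h + 2 * ph, wd + 2 * pw), dtype=x.data.dtype)
        xp[:, :, ph : ph + h, pw : pw + wd] = x.data
    else:
        xp = x.data
    # im2col: (N, C*kh*kw, H*W)
    cols = np.empty((n, c, kh, kw, h, wd), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i * dilation : i * dilation + h, j * dilation : j * dilation + wd]
    cols2 = cols.reshape(n, c * kh * kw, h * wd)
    wmat = w.data.reshape(o, c * kh * kw)
    out = (wmat @ cols2).reshape(n, o, h, wd)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def bwd(g):
        gmat = g.reshape(n, o, h * wd)
        gw = np.einsum("noh,nch->oc", gmat, cols2).reshape(w.shape)
        gcols = (wmat.T @ gmat).reshape(n, c, kh, kw, h, wd)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i * dilation : i * dilation + h, j * dilation : j * dilation + wd] += gcols[:, :, i, j]
        gx = gxp[:, :, ph : ph + h, pw : pw + wd] if (ph or pw) else gxp
        grads = [gx, gw]
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return custom_op(parents, out, bwd)
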