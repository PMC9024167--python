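"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the segmentation network needs:
broadcasting arithmetic, reductions, ReLU/sigmoid/log/pow, concatenation
and reshape, stride-1 "same" dilated N-D convolution, 2x max-pooling and
2x nearest-neighbor upsampling.  Gradients flow through a dynamically
recorded tape; ``Tensor.backward()`` runs the tape in reverse
topological order.

All data is float64: the package favors exactness of its algebraic
identities (residual-identity, telescoping-sum, gradient-footprint
checks) over speed, and the desk-scale problems here are small.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "bce_with_logits", "concat", "convnd", "maxpool2", "upsample2"]


class Tensor:
    """Array node of the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            _accum(self, _unbroadcast(g, self.data.shape))
            _accum(other, _unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            _accum(self, -g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            _accum(self, _unbroadcast(g * other.data, self.data.shape))
            _accum(other, _unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            _accum(self, _unbroadcast(g / other.data, self.data.shape))
            _accum(other, _unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def bwd(g):
            _accum(self, g * exponent * self.data ** (exponent - 1))

        return Tensor(out_data, parents=(self,), backward=bwd)

    # -- elementwise nonlinearities --------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g):
            _accum(self, g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            _accum(self, g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            _accum(self, g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape

        def bwd(g):
            _accum(self, g.reshape(orig))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def bwd(g):
            if axis is None:
                _accum(self, np.broadcast_to(g, shape).copy())
                return
            gg = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % len(shape) for a in axes):
                    gg = np.expand_dims(gg, ax)
            _accum(self, np.broadcast_to(gg, shape).copy())

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    t.grad = g.copy() if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def bce_with_logits(z: Tensor, y: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed from logits.

    Stable for large |z| and, unlike BCE on probabilities, its gradient
    sigmoid(z) - y never vanishes in the saturated regime.
    """
    y = np.asarray(y, dtype=np.float64)
    zd = z.data
    loss = np.maximum(zd, 0.0) - zd * y + np.log1p(np.exp(-np.abs(zd)))
    n = zd.size

    def bwd(g):
        p = 1.0 / (1.0 + np.exp(-zd))
        _accum(z, g * (p - y) / n)

    return Tensor(loss.mean(), parents=(z,), backward=bwd)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis``."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accum(t, g[tuple(idx)])

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


def convnd(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Stride-1 dilated convolution with "same" zero padding.

    x : (N, Cin, *spatial); w : (Cout, Cin, *kernel) with odd kernel
    sides; b : (Cout,) or None.  Output spatial size equals input size
    (padding = dilation * (k - 1) / 2 per dim).
    """
    nd = x.data.ndim - 2
    ksizes = w.data.shape[2:]
    if len(ksizes) != nd:
        raise ValueError("kernel dimensionality does not match input")
    if any(k % 2 == 0 for k in ksizes):
        raise ValueError("kernel sides must be odd")
    if w.data.shape[1] != x.data.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.data.shape[1]}, kernel expects {w.data.shape[1]}"
        )
    pads = [dilation * (k // 2) for k in ksizes]
    spatial = x.data.shape[2:]
    xp = np.pad(x.data, [(0, 0), (0, 0)] + [(p, p) for p in pads])
    n_out = w.data.shape[0]
    out_data = np.zeros((x.data.shape[0], n_out) + spatial)
    taps = list(np.ndindex(*ksizes))
    for t in taps:
        sl = tuple(
            slice(ti * dilation, ti * dilation + s) for ti, s in zip(t, spatial)
        )
        patch = xp[(slice(None), slice(None)) + sl]
        out_data += np.einsum("oc,nc...->no...", w.data[(slice(None), slice(None)) + t], patch)
    if b is not None:
        out_data += b.data.reshape((1, n_out) + (1,) * nd)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        if b is not None:
            _accum(b, g.sum(axis=(0,) + tuple(range(2, g.ndim))))
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(w.data)
        for t in taps:
            sl = tuple(
                slice(ti * dilation, ti * dilation + s) for ti, s in zip(t, spatial)
            )
            patch = xp[(slice(None), slice(None)) + sl]
            sum_axes = (0,) + tuple(range(2, g.ndim))
            dw[(slice(None), slice(None)) + t] = np.tensordot(g, patch, axes=(sum_axes, sum_axes))
            dxp[(slice(None), slice(None)) + sl] += np.einsum(
                "oc,no...->nc...", w.data[(slice(None), slice(None)) + t], g
            )
        _accum(w, dw)
        core = tuple(slice(p, p + s) for p, s in zip(pads, spatial))
        _accum(x, dxp[(slice(None), slice(None)) + core])

    return Tensor(out_data, parents=parents, backward=bwd)


def maxpool2(x: Tensor) -> Tensor:
    """2x max-pooling over every spatial dimension (dims must be even)."""
    nd = x.data.ndim - 2
    spatial = x.data.shape[2:]
    if any(s % 2 for s in spatial):
        raise ValueError(f"spatial dims {spatial} must be even for 2x pooling")
    n, c = x.data.shape[:2]
    halves = tuple(s // 2 for s in spatial)
    # split each spatial axis into (s/2, 2), move the 2s to the back, flatten them
    split_shape = (n, c) + tuple(v for s in halves for v in (s, 2))
    perm = (0, 1) + tuple(2 + 2 * i for i in range(nd)) + tuple(3 + 2 * i for i in range(nd))
    windows = x.data.reshape(split_shape).transpose(perm).reshape((n, c) + halves + (2**nd,))
    arg = windows.argmax(axis=-1)
    out_data = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]

    def bwd(g):
        gw = np.zeros((n, c) + halves + (2**nd,))
        np.put_along_axis(gw, arg[..., None], g[..., None], axis=-1)
        inv = np.argsort(perm)
        gx = gw.reshape((n, c) + halves + (2,) * nd).transpose(inv).reshape(x.data.shape)
        _accum(x, gx)

    return Tensor(out_data, parents=(x,), backward=bwd)


def upsample2(x: Tensor) -> Tensor:
    """2x nearest-neighbor upsampling over every spatial dimension."""
    nd = x.data.ndim - 2
    out_data = x.data
    for ax in range(2, 2 + nd):
        out_data = np.repeat(out_data, 2, axis=ax)

    def bwd(g):
        n, c = x.data.shape[:2]
        spatial = x.data.shape[2:]
        split_shape = (n, c) + tuple(v for s in spatial for v in (s, 2))
        gx = g.reshape(split_shape).sum(axis=tuple(3 + 2 * i for i in range(nd)))
        _accum(x, gx)

    return Tensor(out_data, parents=(x,), backward=bwd)
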