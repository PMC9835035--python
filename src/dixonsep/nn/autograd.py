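"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the 3D convolutional GAN in this package: a
:class:`Tensor` wrapping a float32 ndarray with a gradient slot, primitive
ops (3D convolution and transposed convolution via stride-tricks, pointwise
nonlinearities, concatenation, reductions, feature normalization), and a
topological-order backward pass.

Convolutions use ``numpy.lib.stride_tricks.sliding_window_view`` to expose
kernel neighbourhoods and ``einsum`` for the contractions; the
gradient-to-input scatter loops over the k^3 kernel offsets, which keeps
memory bounded and is fast at the network sizes used here.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor"]

_EINSUM_KW = {"optimize": True}


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        data = a.data + b.data

        def backward(g):
            a._accumulate(_unbroadcast(g, a.data.shape))
            b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(data, (a, b), backward)

    def __sub__(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        data = a.data - b.data

        def backward(g):
            a._accumulate(_unbroadcast(g, a.data.shape))
            b._accumulate(_unbroadcast(-g, b.data.shape))

        return Tensor._make(data, (a, b), backward)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return self.scale(float(other))
        a, b = self, other
        data = a.data * b.data

        def backward(g):
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(data, (a, b), backward)

    __rmul__ = __mul__

    def scale(self, c: float) -> "Tensor":
        a = self
        data = a.data * c

        def backward(g):
            a._accumulate(g * c)

        return Tensor._make(data, (a,), backward)

    # -- pointwise nonlinearities ---------------------------------------
    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        a = self
        data = np.where(a.data > 0, a.data, slope * a.data)

        def backward(g):
            a._accumulate(np.where(a.data > 0, g, slope * g))

        return Tensor._make(data, (a,), backward)

    def relu(self) -> "Tensor":
        return self.leaky_relu(0.0)

    def sigmoid(self) -> "Tensor":
        a = self
        data = _sigmoid(a.data)

        def backward(g):
            a._accumulate(g * data * (1.0 - data))

        return Tensor._make(data, (a,), backward)

    def log(self, eps: float = 1e-7) -> "Tensor":
        a = self
        clipped = np.maximum(a.data, eps)
        data = np.log(clipped)

        def backward(g):
            a._accumulate(np.where(a.data > eps, g / clipped, 0.0))

        return Tensor._make(data, (a,), backward)

    def abs(self) -> "Tensor":
        a = self
        data = np.abs(a.data)

        def backward(g):
            a._accumulate(g * np.sign(a.data))

        return Tensor._make(data, (a,), backward)

    def square(self) -> "Tensor":
        a = self
        data = a.data**2

        def backward(g):
            a._accumulate(2.0 * g * a.data)

        return Tensor._make(data, (a,), backward)

    def sqrt(self, eps: float = 1e-12) -> "Tensor":
        a = self
        data = np.sqrt(a.data + eps)

        def backward(g):
            a._accumulate(g / (2.0 * data))

        return Tensor._make(data, (a,), backward)

    # -- reductions ------------------------------------------------------
    def mean(self, axis=None) -> "Tensor":
        a = self
        data = np.mean(a.data, axis=axis, keepdims=False)
        n = a.data.size if axis is None else np.prod([a.data.shape[ax] for ax in np.atleast_1d(axis)])

        def backward(g):
            if axis is None:
                a._accumulate(np.full_like(a.data, g / n, dtype=np.float32))
            else:
                a._accumulate(np.broadcast_to(np.expand_dims(g, axis) / n, a.data.shape).astype(np.float32))

        return Tensor._make(np.asarray(data, dtype=np.float32), (a,), backward)

    def sum(self) -> "Tensor":
        a = self
        data = np.asarray(a.data.sum(), dtype=np.float32)

        def backward(g):
            a._accumulate(np.full_like(a.data, g))

        return Tensor._make(data, (a,), backward)

    # -- structural ops ---------------------------------------------------
    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 1) -> "Tensor":
        data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

        return Tensor._make(data, tuple(tensors), backward)

    # -- convolutions -----------------------------------------------------
    def conv3d(self, weight: "Tensor", bias: "Tensor | None", stride: int, padding: int) -> "Tensor":
        """3D cross-correlation; input (N,C,D,H,W), weight (O,C,k,k,k)."""
        a, w = self, weight
        xp = _pad3(a.data, padding)
        data = _conv_fw(xp, w.data, stride)
        if bias is not None:
            data = data + bias.data.reshape(1, -1, 1, 1, 1)

        def backward(g):
            if bias is not None:
                bias._accumulate(g.sum(axis=(0, 2, 3, 4)))
            w._accumulate(_conv_bw_weight(xp, g, stride, w.data.shape))
            gx = _conv_bw_input(g, w.data, stride, xp.shape)
            a._accumulate(_crop3(gx, padding))

        parents = (a, w) if bias is None else (a, w, bias)
        return Tensor._make(data, parents, backward)

    def conv_transpose3d(
        self, weight: "Tensor", bias: "Tensor | None", stride: int, padding: int
    ) -> "Tensor":
        """3D transposed convolution; input (N,C,D,H,W), weight (C,O,k,k,k).

        Output spatial edge = (in - 1) * stride + k - 2 * padding.
        """
        a, w = self, weight
        k = w.data.shape[2]
        full = _convT_fw(a.data, w.data, stride, k)
        data = _crop3(full, padding)
        if bias is not None:
            data = data + bias.data.reshape(1, -1, 1, 1, 1)

        def backward(g):
            if bias is not None:
                bias._accumulate(g.sum(axis=(0, 2, 3, 4)))
            gp = _pad3(g, padding)
            # grad wrt input: correlate padded upstream grad with the kernel
            a._accumulate(_conv_fw_transposed_weight(gp, w.data, stride))
            w._accumulate(_convT_bw_weight(a.data, gp, stride, w.data.shape))

        parents = (a, w) if bias is None else (a, w, bias)
        return Tensor._make(data, parents, backward)

    # -- feature normalization -------------------------------------------
    def normalize(self, axes: tuple[int, ...], gamma: "Tensor", beta: "Tensor", eps: float = 1e-5) -> "Tensor":
        """Normalize to zero mean / unit variance over ``axes``, then apply a
        per-channel affine transform (instance or batch norm depending on
        the axes)."""
        a = self
        mu = a.data.mean(axis=axes, keepdims=True)
        var = a.data.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (a.data - mu) * inv
        gshape = [1] * a.data.ndim
        gshape[1] = -1
        gm = gamma.data.reshape(gshape)
        bt = beta.data.reshape(gshape)
        data = gm * xhat + bt
        n = np.prod([a.data.shape[ax] for ax in axes])

        def backward(g):
            sum_axes = tuple(i for i in range(a.data.ndim) if i != 1)
            gamma._accumulate((g * xhat).sum(axis=sum_axes))
            beta._accumulate(g.sum(axis=sum_axes))
            gxhat = g * gm
            # standard normalization backward
            ga = (
                gxhat
                - gxhat.mean(axis=axes, keepdims=True)
                - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True)
            ) * inv
            a._accumulate(ga.astype(np.float32))

        return Tensor._make(data, (a, gamma, beta), backward)


# ---------------------------------------------------------------------------
# low-level convolution kernels
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if g.shape == shape:
        return g
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _pad3(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))


def _crop3(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return x[:, :, p:-p, p:-p, p:-p]


def _strided_view(xp: np.ndarray, k: int, s: int) -> np.ndarray:
    """(N,C,Do,Ho,Wo,k,k,k) sliding view of a padded input."""
    v = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    return v[:, :, ::s, ::s, ::s]


def _conv_fw(xp: np.ndarray, w: np.ndarray, s: int) -> np.ndarray:
    k = w.shape[2]
    v = _strided_view(xp, k, s)
    return np.einsum("ncdhwxyz,ocxyz->nodhw", v, w, **_EINSUM_KW).astype(np.float32)


def _conv_bw_weight(xp: np.ndarray, g: np.ndarray, s: int, wshape) -> np.ndarray:
    k = wshape[2]
    v = _strided_view(xp, k, s)
    return np.einsum("nodhw,ncdhwxyz->ocxyz", g, v, **_EINSUM_KW).astype(np.float32)


def _conv_bw_input(g: np.ndarray, w: np.ndarray, s: int, xp_shape) -> np.ndarray:
    """Scatter upstream grads back onto the (padded) conv input."""
    n, o, do, ho, wo = g.shape
    k = w.shape[2]
    gx = np.zeros(xp_shape, dtype=np.float32)
    for dx in range(k):
        for dy in range(k):
            for dz in range(k):
                contrib = np.einsum("nodhw,oc->ncdhw", g, w[:, :, dx, dy, dz], **_EINSUM_KW)
                gx[:, :, dx : dx + s * do : s, dy : dy + s * ho : s, dz : dz + s * wo : s] += contrib
    return gx


def _convT_fw(x: np.ndarray, w: np.ndarray, s: int, k: int) -> np.ndarray:
    """Transposed-conv forward onto the un-cropped (full) output grid."""
    n, c, d, h, ww = x.shape
    o = w.shape[1]
    full_shape = (n, o, (d - 1) * s + k, (h - 1) * s + k, (ww - 1) * s + k)
    out = np.zeros(full_shape, dtype=np.float32)
    for dx in range(k):
        for dy in range(k):
            for dz in range(k):
                contrib = np.einsum("ncdhw,co->nodhw", x, w[:, :, dx, dy, dz], **_EINSUM_KW)
                out[:, :, dx : dx + s * d : s, dy : dy + s * h : s, dz : dz + s * ww : s] += contrib
    return out


def _conv_fw_transposed_weight(gp: np.ndarray, w: np.ndarray, s: int) -> np.ndarray:
    """Correlation of padded upstream grad with weight (C,O,k,k,k) -> (N,C,...)."""
    k = w.shape[2]
    v = _strided_view(gp, k, s)
    return np.einsum("nodhwxyz,coxyz->ncdhw", v, w, **_EINSUM_KW).astype(np.float32)


def _convT_bw_weight(x: np.ndarray, gp: np.ndarray, s: int, wshape) -> np.ndarray:
    k = wshape[2]
    v = _strided_view(gp, k, s)
    return np.einsum("ncdhw,nodhwxyz->coxyz", x, v, **_EINSUM_KW).astype(np.float32)
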