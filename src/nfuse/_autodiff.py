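"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations the fusion network and its losses need are provided:
elementwise arithmetic, ReLU/clip/abs, reductions, stream-axis max,
channel concatenation, 2-D convolution (stride 1, "same" or "valid"
padding), batch normalization, and two sliding-window primitives used by
the MEF-SSIM loss.  Everything is float64; graphs are built eagerly and
freed after ``backward``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "conv2d",
    "batch_norm",
    "axis_max",
    "stream_max",
    "stream_sum",
    "expand_axis",
    "expand_streams",
    "windowed_sum",
    "window_dot",
]


_grad_enabled = True


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free graph references as we go
            node._backward = None
            node._parents = ()

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        return _binary(self, other, np.add, _bcast_back_add)

    __radd__ = __add__

    def __neg__(self):
        return _unary(self, lambda x: -x, lambda x, g: -g)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _node(self.data * other.data, (self, other))
        if out._parents:
            a_data, b_data = self.data, other.data

            def back(g):
                if self.requires_grad or self._parents:
                    self._accumulate(_unbroadcast(g * b_data, a_data.shape))
                if other.requires_grad or other._parents:
                    other._accumulate(_unbroadcast(g * a_data, b_data.shape))

            out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _node(self.data / other.data, (self, other))
        if out._parents:
            a_data, b_data = self.data, other.data

            def back(g):
                if self.requires_grad or self._parents:
                    self._accumulate(_unbroadcast(g / b_data, a_data.shape))
                if other.requires_grad or other._parents:
                    other._accumulate(
                        _unbroadcast(-g * a_data / (b_data * b_data), b_data.shape)
                    )

            out._backward = back
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        return _unary(self, lambda x: x**e, lambda x, g: g * e * x ** (e - 1.0))

    # -- elementwise nonlinearities ---------------------------------------

    def relu(self):
        return _unary(self, lambda x: np.maximum(x, 0.0), lambda x, g: g * (x > 0))

    def abs(self):
        return _unary(self, np.abs, lambda x, g: g * np.sign(x))

    def clip(self, lo: float, hi: float):
        return _unary(
            self,
            lambda x: np.clip(x, lo, hi),
            lambda x, g: g * ((x >= lo) & (x <= hi)),
        )

    def sqrt(self):
        return _unary(self, np.sqrt, lambda x, g: g * 0.5 / np.sqrt(x))

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None):
        out = _node(self.data.sum(axis=axis), (self,))
        if out._parents:
            shape = self.data.shape

            def back(g):
                if axis is None:
                    self._accumulate(np.broadcast_to(g, shape))
                else:
                    self._accumulate(np.broadcast_to(np.expand_dims(g, axis), shape))

            out._backward = back
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        if out._parents:
            orig = self.data.shape
            out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    if _grad_enabled:
        out._parents = tuple(p for p in parents if p.requires_grad or p._parents)
    return out


def _unary(a: Tensor, fwd, back) -> Tensor:
    out = _node(fwd(a.data), (a,))
    if out._parents:
        x = a.data
        out._backward = lambda g: a._accumulate(back(x, g))
    return out


def _bcast_back_add(a: Tensor, b: Tensor, g: np.ndarray):
    if a.requires_grad or a._parents:
        a._accumulate(_unbroadcast(g, a.data.shape))
    if b.requires_grad or b._parents:
        b._accumulate(_unbroadcast(g, b.data.shape))


def _binary(a: Tensor, other, fwd, back) -> Tensor:
    b = _as_tensor(other)
    out = _node(fwd(a.data, b.data), (a, b))
    if out._parents:
        out._backward = lambda g: back(a, b, g)
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum g down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- structural ops -------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def back(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad or t._parents:
                    t._accumulate(piece)

        out._backward = back
    return out


def axis_max(x: Tensor, axis: int = 0) -> Tensor:
    """Element-wise max over one axis.

    The subgradient of a tie is routed to the first attaining element
    along the axis (argmax convention).
    """
    if x.data.shape[axis] < 1:
        raise ValueError("axis_max needs a non-empty axis")
    idx = np.argmax(x.data, axis=axis)
    out = _node(
        np.take_along_axis(x.data, np.expand_dims(idx, axis), axis=axis).squeeze(axis),
        (x,),
    )
    if out._parents:
        shape = x.data.shape

        def back(g):
            gx = np.zeros(shape)
            np.put_along_axis(
                gx, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis
            )
            x._accumulate(gx)

        out._backward = back
    return out


def stream_max(x: Tensor) -> Tensor:
    """Element-wise max over axis 0 (the stream axis)."""
    return axis_max(x, 0)


def stream_sum(x: Tensor) -> Tensor:
    """Sum over axis 0 — the sum-pooling aggregator used in ablations."""
    return x.sum(axis=0)


def expand_axis(x: Tensor, n: int, axis: int = 0) -> Tensor:
    """Insert a broadcast axis of length n (backward sums over it)."""
    shape = x.data.shape[:axis] + (n,) + x.data.shape[axis:]
    out = _node(np.broadcast_to(np.expand_dims(x.data, axis), shape).copy(), (x,))
    if out._parents:
        out._backward = lambda g: x._accumulate(g.sum(axis=axis))
    return out


def expand_streams(x: Tensor, n: int) -> Tensor:
    """Broadcast a pooled (C,H,W) tensor to (n,C,H,W)."""
    return expand_axis(x, n, 0)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: str = "same") -> Tensor:
    """2-D convolution (cross-correlation), stride 1.

    x: (B, Cin, H, W); w: (Cout, Cin, kh, kw); b: (Cout,) or None.
    ``same`` keeps H×W (odd kernels only); ``valid`` shrinks by k−1.
    """
    B, Cin, H, W = x.data.shape
    Cout, Cin_w, kh, kw = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, kernel expects {Cin_w}")
    if padding == "same":
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("'same' padding requires odd kernels")
        ph, pw = kh // 2, kw // 2
    elif padding == "valid":
        ph = pw = 0
    else:
        raise ValueError(f"unknown padding {padding!r}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Ho, Wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    # (B, Cin, Ho, Wo, kh, kw) -> (B, Ho*Wo, Cin*kh*kw)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, Cin * kh * kw)
    wmat = w.data.reshape(Cout, -1)
    y = cols @ wmat.T  # (B, Ho*Wo, Cout)
    if b is not None:
        y = y + b.data
    out = _node(
        y.transpose(0, 2, 1).reshape(B, Cout, Ho, Wo),
        (x, w) if b is None else (x, w, b),
    )
    if out._parents:

        def back(g):
            gm = g.reshape(B, Cout, Ho * Wo).transpose(0, 2, 1)  # (B,HoWo,Cout)
            if w.requires_grad or w._parents:
                gw = np.einsum("bpo,bpk->ok", gm, cols)
                w._accumulate(gw.reshape(w.data.shape))
            if b is not None and (b.requires_grad or b._parents):
                b._accumulate(gm.sum(axis=(0, 1)))
            if x.requires_grad or x._parents:
                gcols = gm @ wmat  # (B, HoWo, Cin*kh*kw)
                gcols = gcols.reshape(B, Ho, Wo, Cin, kh, kw)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i : i + Ho, j : j + Wo] += gcols[
                            :, :, :, :, i, j
                        ].transpose(0, 3, 1, 2)
                x._accumulate(
                    gxp[:, :, ph : ph + H, pw : pw + W]
                    if (ph or pw)
                    else gxp
                )

        out._backward = back
    return out


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
    update_stats: bool = True,
) -> Tensor:
    """Per-channel batch normalization over (batch, H, W).

    Streams are folded into the batch axis by the caller, so the statistics
    pool over all streams and spatial positions.  Running statistics use the
    biased batch variance and are updated in place when ``training`` and
    ``update_stats`` are both true; inference normalizes with the stored
    running statistics.
    """
    axes = (0, 2, 3)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        if update_stats:
            running_mean *= 1.0 - momentum
            running_mean += momentum * mean
            running_var *= 1.0 - momentum
            running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out = _node(xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None],
                (x, gamma, beta))
    if out._parents:
        n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

        def back(g):
            if gamma.requires_grad or gamma._parents:
                gamma._accumulate((g * xhat).sum(axis=axes))
            if beta.requires_grad or beta._parents:
                beta._accumulate(g.sum(axis=axes))
            if x.requires_grad or x._parents:
                gxhat = g * gamma.data[None, :, None, None]
                if training:
                    s1 = gxhat.sum(axis=axes)
                    s2 = (gxhat * xhat).sum(axis=axes)
                    gx = (
                        gxhat
                        - s1[None, :, None, None] / n
                        - xhat * s2[None, :, None, None] / n
                    ) * inv_std[None, :, None, None]
                else:
                    gx = gxhat * inv_std[None, :, None, None]
                x._accumulate(gx)

        out._backward = back
    return out


def windowed_sum(x: Tensor, window: int, stride: int = 1) -> Tensor:
    """Sum of each sliding window of a 2-D tensor -> (nH, nW) grid."""
    v = sliding_window_view(x.data, (window, window))[::stride, ::stride]
    out = _node(v.sum(axis=(2, 3)), (x,))
    if out._parents:
        shape = x.data.shape
        nH, nW = out.data.shape

        def back(g):
            gx = np.zeros(shape)
            for i in range(window):
                for j in range(window):
                    gx[i : i + nH * stride : stride, j : j + nW * stride : stride] += g
            x._accumulate(gx)

        out._backward = back
    return out


def window_dot(x: Tensor, kernels: np.ndarray, stride: int = 1) -> Tensor:
    """Per-window dot product with a per-window constant kernel.

    kernels: (nH, nW, w, w), constant with respect to differentiation.
    Returns the (nH, nW) grid of <window of x, kernel>.
    """
    w = kernels.shape[2]
    v = sliding_window_view(x.data, (w, w))[::stride, ::stride]
    if v.shape != kernels.shape:
        raise ValueError(f"kernel grid {kernels.shape} != window grid {v.shape}")
    out = _node(np.einsum("ijkl,ijkl->ij", v, kernels), (x,))
    if out._parents:
        shape = x.data.shape
        nH, nW = out.data.shape

        def back(g):
            gx = np.zeros(shape)
            gk = g[:, :, None, None] * kernels
            for i in range(w):
                for j in range(w):
                    gx[i : i + nH * stride : stride, j : j + nW * stride : stride] += gk[
                        :, :, i, j
                    ]
            x._accumulate(gx)

        out._backward = back
    return out
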