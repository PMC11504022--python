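"""Minimal reverse-mode autograd over numpy arrays.

Supports exactly the operations the screening models need: broadcasting
elementwise arithmetic, batched matmul, reductions, reshapes, slicing,
concatenation, the smooth activations, and convolution / adaptive-pooling
primitives with hand-written backward passes.  Gradient correctness is
checked against finite differences in the test suite.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["Tensor", "concatenate", "stack", "softmax", "minimum", "maximum",
           "conv2d", "conv3d", "conv1d",
           "adaptive_avg_pool2d", "adaptive_max_pool2d", "bilinear_resize"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce ``grad`` back to ``shape`` after numpy broadcasting."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = (), _backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = _backward
        self._prev = _prev

    # -- plumbing ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.result_type(self.data.dtype, np.float32))
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        visited: set[int] = set()
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
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(-g)
        out._backward = _bw
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1.0))
        out._backward = _bw
        return out

    # -- transcendental / activations -------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * y)
        out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)
        out._backward = _bw
        return out

    def sqrt(self):
        return self ** 0.5

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * y * (1.0 - y))
        out._backward = _bw
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - y * y))
        out._backward = _bw
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)
        out._backward = _bw
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * (s * (1.0 + self.data * (1.0 - s))))
        out._backward = _bw
        return out

    def gelu(self):
        # tanh approximation; smooth-gated activation used by the classifier
        c = np.sqrt(2.0 / np.pi).astype(self.data.dtype) if hasattr(np.sqrt(2.0 / np.pi), "astype") else np.sqrt(2.0 / np.pi)
        x = self.data
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out = Tensor(0.5 * x * (1.0 + t), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                dt = (1.0 - t * t) * c * (1.0 + 3 * 0.044715 * x ** 2)
                self._accumulate(g * (0.5 * (1.0 + t) + 0.5 * x * dt))
        out._backward = _bw
        return out

    def softplus(self):
        y = np.logaddexp(0.0, self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g / (1.0 + np.exp(-self.data)))
        out._backward = _bw
        return out

    def arctan(self):
        out = Tensor(np.arctan(self.data), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g / (1.0 + self.data ** 2))
        out._backward = _bw
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        m = self.data.max(axis=axis, keepdims=True)
        out = Tensor(m if keepdims else np.squeeze(m, axis=axis), self.requires_grad, (self,))
        mask = (self.data == m)
        counts = mask.sum(axis=axis, keepdims=True)

        def _bw(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(mask * (g / counts))
        out._backward = _bw
        return out

    # -- shape manipulation ------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))
        out._backward = _bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))
        out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data, dtype=g.dtype)
                np.add.at(full, idx, g)
                self._accumulate(full)
        out._backward = _bw
        return out

    # -- matmul ------------------------------------------------------------
    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(np.matmul(self.data, other.data),
                     self.requires_grad or other.requires_grad, (self, other))

        def _bw(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.multiply.outer(g, other.data) if g.ndim else g * other.data
                else:
                    ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.multiply.outer(self.data, g)
                else:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.data.shape))
        out._backward = _bw
        return out


# -- free functions --------------------------------------------------------

def minimum(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor._lift(a), Tensor._lift(b)
    mask = a.data <= b.data
    out = Tensor(np.where(mask, a.data, b.data), a.requires_grad or b.requires_grad, (a, b))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * ~mask, b.data.shape))
    out._backward = _bw
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor._lift(a), Tensor._lift(b)
    mask = a.data >= b.data
    out = Tensor(np.where(mask, a.data, b.data), a.requires_grad or b.requires_grad, (a, b))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * ~mask, b.data.shape))
    out._backward = _bw
    return out


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])
    out._backward = _bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = Tensor._lift(t)
        shape = list(t.data.shape)
        shape.insert(axis if axis >= 0 else t.data.ndim + 1 + axis, 1)
        expanded.append(t.reshape(shape))
    return concatenate(expanded, axis=axis)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, no grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


# -- convolution primitives -------------------------------------------------

def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride=1, padding=0) -> Tensor:
    """x: (N, C, H, W); w: (Cout, C, kh, kw); b: (Cout,) or None."""
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    N, C, H, W = x.data.shape
    Cout, _, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    OH = (H + 2 * ph - kh) // sh + 1
    OW = (W + 2 * pw - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]                      # (N, C, OH, OW, kh, kw)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(N, C * kh * kw, OH * OW)
    wmat = w.data.reshape(Cout, C * kh * kw)
    y = np.matmul(wmat, cols)                        # (N, Cout, OH*OW)
    if b is not None:
        y = y + b.data[None, :, None]
    out = Tensor(y.reshape(N, Cout, OH, OW),
                 x.requires_grad or w.requires_grad or (b is not None and b.requires_grad),
                 tuple(t for t in (x, w, b) if t is not None))

    def _bw(g):
        gflat = g.reshape(N, Cout, OH * OW)
        if b is not None and b.requires_grad:
            b._accumulate(gflat.sum(axis=(0, 2)))
        if w.requires_grad:
            gw = np.einsum("nol,nkl->ok", gflat, cols)
            w._accumulate(gw.reshape(w.data.shape))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gflat)         # (N, C*kh*kw, OH*OW)
            gcols = gcols.reshape(N, C, kh, kw, OH, OW)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + sh * OH:sh, j:j + sw * OW:sw] += gcols[:, :, i, j]
            x._accumulate(gxp[:, :, ph:ph + H, pw:pw + W])
    out._backward = _bw
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride=(1, 1, 1), padding=(0, 0, 0)) -> Tensor:
    """x: (N, C, D, H, W); w: (Cout, C, kd, kh, kw)."""
    sd, sh, sw = stride
    pd, ph, pw = padding
    N, C, D, H, W = x.data.shape
    Cout, _, kd, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    OD = (D + 2 * pd - kd) // sd + 1
    OH = (H + 2 * ph - kh) // sh + 1
    OW = (W + 2 * pw - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
    win = win[:, :, ::sd, ::sh, ::sw]                # (N,C,OD,OH,OW,kd,kh,kw)
    cols = win.transpose(0, 1, 5, 6, 7, 2, 3, 4).reshape(N, C * kd * kh * kw, OD * OH * OW)
    wmat = w.data.reshape(Cout, C * kd * kh * kw)
    y = np.matmul(wmat, cols)
    if b is not None:
        y = y + b.data[None, :, None]
    out = Tensor(y.reshape(N, Cout, OD, OH, OW),
                 x.requires_grad or w.requires_grad or (b is not None and b.requires_grad),
                 tuple(t for t in (x, w, b) if t is not None))

    def _bw(g):
        gflat = g.reshape(N, Cout, OD * OH * OW)
        if b is not None and b.requires_grad:
            b._accumulate(gflat.sum(axis=(0, 2)))
        if w.requires_grad:
            gw = np.einsum("nol,nkl->ok", gflat, cols)
            w._accumulate(gw.reshape(w.data.shape))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gflat).reshape(N, C, kd, kh, kw, OD, OH, OW)
            gxp = np.zeros_like(xp)
            for a in range(kd):
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, a:a + sd * OD:sd, i:i + sh * OH:sh, j:j + sw * OW:sw] += \
                            gcols[:, :, a, i, j]
            x._accumulate(gxp[:, :, pd:pd + D, ph:ph + H, pw:pw + W])
    out._backward = _bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """x: (N, C, L); w: (Cout, C, k). Implemented through conv2d on a height-1 grid."""
    x4 = x.reshape(x.shape[0], x.shape[1], 1, x.shape[2])
    w4 = w.reshape(w.shape[0], w.shape[1], 1, w.shape[2])
    y = conv2d(x4, w4, b, stride=(1, stride), padding=(0, padding))
    return y.reshape(y.shape[0], y.shape[1], y.shape[3])


# -- pooling / resizing -----------------------------------------------------

def _bins(n_in: int, n_out: int) -> list[tuple[int, int]]:
    return [((i * n_in) // n_out, -((-(i + 1) * n_in) // n_out)) for i in range(n_out)]


def adaptive_avg_pool2d(x: Tensor, out_hw) -> Tensor:
    oh, ow = _pair(out_hw)
    N, C, H, W = x.data.shape
    hb, wb = _bins(H, oh), _bins(W, ow)
    y = np.empty((N, C, oh, ow), dtype=x.data.dtype)
    for i, (h0, h1) in enumerate(hb):
        for j, (w0, w1) in enumerate(wb):
            y[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))
    out = Tensor(y, x.requires_grad, (x,))

    def _bw(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                area = (h1 - h0) * (w1 - w0)
                gx[:, :, h0:h1, w0:w1] += g[:, :, i, j][:, :, None, None] / area
        x._accumulate(gx)
    out._backward = _bw
    return out


def adaptive_max_pool2d(x: Tensor, out_hw) -> Tensor:
    oh, ow = _pair(out_hw)
    N, C, H, W = x.data.shape
    hb, wb = _bins(H, oh), _bins(W, ow)
    y = np.empty((N, C, oh, ow), dtype=x.data.dtype)
    argmaxes = {}
    for i, (h0, h1) in enumerate(hb):
        for j, (w0, w1) in enumerate(wb):
            patch = x.data[:, :, h0:h1, w0:w1].reshape(N, C, -1)
            idx = patch.argmax(axis=2)
            y[:, :, i, j] = np.take_along_axis(patch, idx[:, :, None], axis=2)[:, :, 0]
            argmaxes[(i, j)] = idx
    out = Tensor(y, x.requires_grad, (x,))

    def _bw(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                bw_ = w1 - w0
                idx = argmaxes[(i, j)]
                rows = h0 + idx // bw_
                cols = w0 + idx % bw_
                n_idx, c_idx = np.meshgrid(np.arange(N), np.arange(C), indexing="ij")
                np.add.at(gx, (n_idx, c_idx, rows, cols), g[:, :, i, j])
        x._accumulate(gx)
    out._backward = _bw
    return out


def _resize_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Row-interpolation matrix for align_corners=False bilinear resizing."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    for i in range(n_out):
        src = (i + 0.5) * n_in / n_out - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        t = src - lo
        m[i, lo] += 1.0 - t
        m[i, hi] += t
    return m


def bilinear_resize(x: Tensor, out_hw, mode: str = "bilinear") -> Tensor:
    """Resize the trailing two axes of (N, C, H, W).  Separable: two constant matmuls."""
    oh, ow = _pair(out_hw)
    N, C, H, W = x.data.shape
    if mode == "nearest":
        ri = ((np.arange(oh) + 0.5) * H / oh).astype(int).clip(0, H - 1)
        ci = ((np.arange(ow) + 0.5) * W / ow).astype(int).clip(0, W - 1)
        R = np.zeros((oh, H), dtype=x.data.dtype)
        R[np.arange(oh), ri] = 1.0
        Cm = np.zeros((ow, W), dtype=x.data.dtype)
        Cm[np.arange(ow), ci] = 1.0
    else:
        R = _resize_matrix(H, oh, x.data.dtype)
        Cm = _resize_matrix(W, ow, x.data.dtype)
    y = Tensor(R) @ x @ Tensor(Cm.T)
    return y
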