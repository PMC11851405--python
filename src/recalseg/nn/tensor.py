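"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the operations the segmentation networks need:
broadcast arithmetic, matmul, 3D convolution (stride 1/2), trilinear
upsampling by 2, softmax/sigmoid/relu, reductions and reshapes.  Gradients
are accumulated by a topological backward sweep over the recorded graph.
All arrays are float32 unless stated otherwise.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "concat", "conv3d", "upsample_trilinear2x", "softmax",
]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float32, copy=False)
    return np.asarray(x, dtype=np.float32)


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
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen:
                        stack.append((p, False))

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free graph references so intermediate buffers can be collected
        for node in topo:
            node._backward = None
            node._parents = ()

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)
        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._make(data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(data, (self, other), backward)

    # -------------------------------------------------------------- pointwise
    def relu(self):
        mask = self.data > 0
        data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(data, (self,), backward)

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * data * (1.0 - data))

        return Tensor._make(data, (self,), backward)

    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * data)

        return Tensor._make(data, (self,), backward)

    def log(self, floor: float = 0.0):
        """Natural log; values below `floor` are clamped (zero gradient there)."""
        if floor > 0.0:
            clipped = np.maximum(self.data, floor)
            pass_mask = self.data >= floor
        else:
            clipped = self.data
            pass_mask = None
        data = np.log(clipped)

        def backward(g):
            if self.requires_grad:
                gi = g / clipped
                if pass_mask is not None:
                    gi = gi * pass_mask
                self._accum(gi)

        return Tensor._make(data, (self,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, tuple(a % self.data.ndim for a in axes))
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ----------------------------------------------------------------- shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(data, (self,), backward)

    def transpose(self, axes):
        data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(data, (self,), backward)

    def __getitem__(self, idx):
        data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accum(full)

        return Tensor._make(data, (self,), backward)


# --------------------------------------------------------------------- joins
def concat(tensors: list, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(data, tuple(tensors), backward)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accum(s * (g - dot))

    return Tensor._make(s, (x,), backward)


# --------------------------------------------------------------- convolution
def _im2col(xp: np.ndarray, k: tuple, stride: int):
    """xp: padded input (B,C,D,H,W) -> col (B, Do, Ho, Wo, C*kd*kh*kw)."""
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(xp, k, axis=(2, 3, 4))  # B,C,Do',Ho',Wo',kd,kh,kw
    if stride > 1:
        win = win[:, :, ::stride, ::stride, ::stride]
    b, c, do, ho, wo = win.shape[:5]
    # -> B,Do,Ho,Wo,C,kd,kh,kw  -> flatten tail
    col = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(b, do, ho, wo, -1)
    return np.ascontiguousarray(col)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """3D cross-correlation: x (B,Cin,D,H,W), w (Cout,Cin,kd,kh,kw)."""
    B, Cin, D, H, W = x.data.shape
    Cout, Cin_w, kd, kh, kw = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"conv3d channel mismatch: input {Cin}, weight {Cin_w}")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x.data
    col = _im2col(xp, (kd, kh, kw), stride)           # B,Do,Ho,Wo,K
    Do, Ho, Wo = col.shape[1:4]
    wflat = w.data.reshape(Cout, -1)                   # Cout,K
    out = col @ wflat.T                                # B,Do,Ho,Wo,Cout
    if b is not None:
        out += b.data
    out = np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))

    def backward(g):
        gperm = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1))  # B,Do,Ho,Wo,Cout
        if w.requires_grad:
            gw = np.tensordot(gperm, col, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
            w._accum(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gperm.sum(axis=(0, 1, 2, 3)))
        if x.requires_grad:
            # scatter per kernel offset: avoids materializing the full
            # (B,Do,Ho,Wo,Cin*k^3) column gradient
            gxp = np.zeros_like(xp)
            s = stride
            wk = w.data.transpose(2, 3, 4, 0, 1)       # kd,kh,kw,Cout,Cin
            for i in range(kd):
                for j in range(kh):
                    for l in range(kw):
                        contrib = gperm @ wk[i, j, l]  # B,Do,Ho,Wo,Cin
                        gxp[:, :, i:i + s * Do:s, j:j + s * Ho:s,
                            l:l + s * Wo:s] += contrib.transpose(0, 4, 1, 2, 3)
            gx = gxp[:, :, p:p + D, p:p + H, p:p + W] if p else gxp
            x._accum(gx)

    return Tensor._make(out, (x, w) if b is None else (x, w, b), backward)


# ---------------------------------------------------------------- upsampling
_INTERP_CACHE: dict[int, np.ndarray] = {}


def _interp_matrix(n: int) -> np.ndarray:
    """Linear-interpolation matrix (2n x n) for factor-2 upsampling.

    Output sample 2i sits at input coordinate i - 0.25, sample 2i+1 at
    i + 0.25 (half-pixel alignment), with edge clamping.
    """
    if n in _INTERP_CACHE:
        return _INTERP_CACHE[n]
    M = np.zeros((2 * n, n), dtype=np.float32)
    for o in range(2 * n):
        src = (o + 0.5) / 2.0 - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n - 1)
        hi_c = min(max(lo + 1, 0), n - 1)
        M[o, lo_c] += 1.0 - frac
        M[o, hi_c] += frac
    _INTERP_CACHE[n] = M
    return M


def upsample_trilinear2x(x: Tensor) -> Tensor:
    """Trilinear upsampling by a factor of 2 along each spatial axis."""
    B, C, D, H, W = x.data.shape
    mats = [_interp_matrix(n) for n in (D, H, W)]

    def apply(data, transpose_m):
        out = data
        for ax, M in zip((2, 3, 4), mats):
            Mx = M.T if transpose_m else M
            out = np.moveaxis(np.tensordot(out, Mx, axes=([ax], [1])), -1, ax)
        return np.ascontiguousarray(out)

    data = apply(x.data, transpose_m=False)

    def backward(g):
        if x.requires_grad:
            x._accum(apply(g, transpose_m=True))

    return Tensor._make(data, (x,), backward)
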