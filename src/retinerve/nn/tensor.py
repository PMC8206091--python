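"""A compact reverse-mode automatic differentiation core on numpy arrays.

Only the operations the package's architectures need are implemented:
elementwise arithmetic with broadcasting, ReLU, matrix multiply, 1D
convolution (via strided im2col + BLAS matmul), 1D max pooling, slicing,
concatenation, reshape and reductions.  Gradients are accumulated by a
topological backward sweep over the recorded graph.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "concatenate", "no_grad"]

#: im2col buffers are blocked to about this many elements (~8 MB float32)
#: so convolution working sets stay cache-resident.
_CHUNK_ELEMS = 2_000_000

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: Optional[np.ndarray] = None
        self._parents: Tuple["Tensor", ...] = ()
        self._backward: Optional[Callable[[np.ndarray], None]] = None

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def _accum_owned(self, grad: np.ndarray) -> None:
        """Accumulate a freshly allocated gradient (no defensive copy)."""
        if self.grad is None:
            self.grad = grad if grad.dtype == self.data.dtype \
                else grad.astype(self.data.dtype)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Run the reverse sweep from this tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def square(self):
        def backward(g):
            self._accum(2.0 * g * self.data)

        return Tensor._make(self.data**2, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0)

        def backward(g):
            self._accum_owned(np.where(self.data > 0, g, self.data.dtype.type(0)))

        return Tensor._make(out_data, (self,), backward)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum_owned(full)

        return Tensor._make(out_data, (self,), backward)

    def sum(self, axis=None):
        out_data = self.data.sum(axis=axis)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                self._accum(np.broadcast_to(np.expand_dims(g, axis), self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    # -- linear algebra ----------------------------------------------------

    def matmul(self, other: "Tensor"):
        """Matrix product; supports (2D @ 2D) and matrix-vector (2D @ 1D)."""
        other = Tensor._lift(other)
        out_data = self.data @ other.data
        vec = other.data.ndim == 1

        def backward(g):
            if self.requires_grad:
                self._accum(np.outer(g, other.data) if vec
                            else g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.T @ g if vec
                             else self.data.swapaxes(-1, -2) @ g)

        return Tensor._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- 1D convolution and pooling ---------------------------------------

    def conv1d(self, weight: "Tensor", bias: Optional["Tensor"] = None,
               stride: int = 1, padding: Tuple[int, int] = (0, 0)) -> "Tensor":
        """Cross-correlation along the length axis, channels last.

        self: (B, L, C_in); weight: (C_out, C_in, K); bias: (C_out,).
        Channels-last keeps each im2col window row contiguous in memory, so
        the gather feeding the BLAS matmul is near-memcpy.
        """
        x = self.data
        w = weight.data
        B, L, C_in = x.shape
        C_out, C_in_w, K = w.shape
        if C_in_w != C_in:
            raise ValueError(f"channel mismatch: input {C_in}, weight {C_in_w}")
        pl, pr = padding
        if pl or pr:
            xp = np.zeros((B, L + pl + pr, C_in), dtype=x.dtype)
            xp[:, pl:L + pl, :] = x
        else:
            xp = np.ascontiguousarray(x)
        Lp = xp.shape[1]
        L_out = (Lp - K) // stride + 1
        w2 = np.ascontiguousarray(w.transpose(2, 1, 0).reshape(K * C_in, C_out))
        row = K * C_in
        # block over the batch so the im2col buffer stays cache-resident;
        # the gather is recomputed in backward instead of being retained
        bc = max(1, _CHUNK_ELEMS // max(1, L_out * row))

        def gather(dst, xpc, nb):
            s0, s1, s2 = xpc.strides
            if stride == 1:
                # each window is a contiguous K*C_in block of the source
                win = np.lib.stride_tricks.as_strided(
                    xpc, shape=(nb, L_out, row), strides=(s0, s1, s2))
                dst[:nb] = win
            else:
                win4 = np.lib.stride_tricks.as_strided(
                    xpc, shape=(nb, L_out, K, C_in),
                    strides=(s0, s1 * stride, s1, s2))
                dst[:nb].reshape(nb, L_out, K, C_in)[...] = win4
            return dst[:nb]

        buf = np.empty((bc, L_out, row), dtype=x.dtype)
        out = np.empty((B, L_out, C_out), dtype=x.dtype)
        for b0 in range(0, B, bc):
            nb = min(bc, B - b0)
            cols = gather(buf, xp[b0:b0 + nb], nb)
            np.matmul(cols.reshape(nb * L_out, row), w2,
                      out=out[b0:b0 + nb].reshape(nb * L_out, C_out))
        if bias is not None:
            out += bias.data

        def backward(g):
            need_x = self.requires_grad
            gw2 = np.zeros_like(w2) if weight.requires_grad else None
            gxp = np.zeros((B, Lp, C_in), dtype=x.dtype) if need_x else None
            bbuf = np.empty((bc, L_out, row), dtype=x.dtype) if weight.requires_grad else None
            for b0 in range(0, B, bc):
                nb = min(bc, B - b0)
                g2 = g[b0:b0 + nb].reshape(nb * L_out, C_out)
                if weight.requires_grad:
                    cols = gather(bbuf, xp[b0:b0 + nb], nb)
                    gw2 += cols.reshape(nb * L_out, row).T @ g2
                if need_x:
                    # input gradient as K shift-accumulated gemms: each
                    # contribution is a contiguous slab add, no scatter
                    gslab = gxp[b0:b0 + nb]
                    for k in range(K):
                        wk = w2[k * C_in:(k + 1) * C_in, :]
                        contrib = (g2 @ wk.T).reshape(nb, L_out, C_in)
                        gslab[:, k:k + L_out * stride:stride, :] += contrib
            if weight.requires_grad:
                weight._accum(gw2.reshape(K, C_in, C_out).transpose(2, 1, 0))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 1)))
            if need_x:
                self._accum_owned(np.ascontiguousarray(gxp[:, pl:L + pl, :]) if pl or pr else gxp)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out, parents, backward)

    def maxpool1d(self, size: int, stride: Optional[int] = None) -> "Tensor":
        """Max pooling along the length axis; self: (B, L, C)."""
        stride = size if stride is None else stride
        x = self.data
        B, L, C = x.shape
        L_out = (L - size) // stride + 1
        if size == 2:
            # all pools in this package are width 2: pairwise maximum on
            # strided views avoids the generic argmax machinery entirely
            a = x[:, 0:(L_out - 1) * stride + 1:stride, :]
            b = x[:, 1:(L_out - 1) * stride + 2:stride, :]
            out = np.maximum(a, b)

            def backward2(g):
                mask = a >= b  # ties route to the earlier sample
                gx = np.zeros_like(x)
                ga = g * mask
                gb = g - ga
                if stride >= 2:
                    gx[:, 0:(L_out - 1) * stride + 1:stride, :] = ga
                    gx[:, 1:(L_out - 1) * stride + 2:stride, :] = gb
                else:
                    gx[:, 0:L_out, :] += ga
                    gx[:, 1:L_out + 1, :] += gb
                self._accum_owned(gx)

            return Tensor._make(out, (self,), backward2)
        xc = np.ascontiguousarray(x)
        s0, s1, s2 = xc.strides
        win = np.lib.stride_tricks.as_strided(
            xc, shape=(B, L_out, size, C), strides=(s0, s1 * stride, s1, s2)
        )
        arg = win.argmax(axis=2)  # (B, L_out, C)
        out = np.take_along_axis(win, arg[:, :, None, :], axis=2)[:, :, 0, :]

        def backward(g):
            gx = np.zeros_like(xc)
            if stride >= size:
                # non-overlapping windows: direct scatter into a view
                view = gx[:, :L_out * stride, :].reshape(B, L_out, stride, C)
                np.put_along_axis(view, arg[:, :, None, :], g[:, :, None, :], axis=2)
            else:
                pos = arg + stride * np.arange(L_out)[None, :, None]
                bidx = np.arange(B)[:, None, None]
                cidx = np.arange(C)[None, None, :]
                np.add.at(gx, (bidx, pos, cidx), g)
            self._accum_owned(gx)

        return Tensor._make(out, (self,), backward)


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along an axis, differentiably."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)
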