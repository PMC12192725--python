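"""Reverse-mode automatic differentiation on NumPy arrays.

A minimal tape: every operation builds a node holding its inputs and a
closure that maps the output cotangent to input cotangents.  ``backward``
on a scalar walks the graph in reverse topological order and accumulates
``.grad`` on every tensor with ``requires_grad``.

Only the primitives the segmentation network needs are provided; anything
composite (batch norm, layer norm, GELU, losses) is built from them in
:mod:`rmisnet.nn` so gradient correctness is centralised here and checked
once by finite differences.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import special

__all__ = ["Tensor", "concat", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An n-d array plus optional gradient tape bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def _coerce(self, x) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        if isinstance(x, (int, float)):
            # scalars adopt this tensor's dtype so float32 nets stay float32
            return Tensor(np.asarray(x, dtype=self.dtype))
        return Tensor(np.asarray(x))

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._make(out_data, (self, other), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(orig),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.shape

        def backward(g):
            full = np.zeros(shape, dtype=g.dtype)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(out_data, (self,), backward)

    def pad2d(self, pad: int):
        """Zero-pad the two trailing (spatial) axes by ``pad`` on each side."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        out_data = np.pad(self.data, width)
        sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
        return Tensor._make(out_data, (self,), lambda g: (g[sl],))

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise nonlinearities ---------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def erf(self):
        x = self.data

        def backward(g):
            return (g * (2.0 / np.sqrt(np.pi)) * np.exp(-(x**2)),)

        return Tensor._make(special.erf(x), (self,), backward)

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        out_data = special.expit(self.data)

        def backward(g):
            return (g * out_data * (1.0 - out_data),)

        return Tensor._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside the interval."""
        inside = (self.data >= lo) & (self.data <= hi)
        out_data = np.clip(self.data, lo, hi)
        return Tensor._make(out_data, (self,), lambda g: (g * inside,))

    # -- structured primitives -------------------------------------------------
    def im2col(self, ksize: int, stride: int, pad: int):
        """Unfold (B, C, H, W) into (B, C*k*k, L) patch columns."""
        b, c, h, w = self.shape
        hp, wp = h + 2 * pad, w + 2 * pad
        ho = (hp - ksize) // stride + 1
        wo = (wp - ksize) // stride + 1
        x = np.pad(self.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        win = sliding_window_view(x, (ksize, ksize), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]  # (B, C, Ho, Wo, k, k)
        cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * ksize * ksize, ho * wo)

        def backward(g):
            gw = g.reshape(b, c, ksize, ksize, ho, wo)
            full = np.zeros((b, c, hp, wp), dtype=g.dtype)
            for i in range(ksize):
                for j in range(ksize):
                    full[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += gw[
                        :, :, i, j
                    ]
            if pad:
                full = full[:, :, pad:-pad, pad:-pad]
            return (full,)

        out = Tensor._make(np.ascontiguousarray(cols), (self,), backward)
        return out, (ho, wo)

    def maxpool2x2(self):
        """2x2 max pooling with stride 2; requires even spatial dims."""
        b, c, h, w = self.shape
        if h % 2 or w % 2:
            raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
        r = self.data.reshape(b, c, h // 2, 2, w // 2, 2)
        r = r.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
        idx = r.argmax(axis=-1)
        out_data = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            gr = np.zeros((b, c, h // 2, w // 2, 4), dtype=g.dtype)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gr = gr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            return (gr.reshape(b, c, h, w),)

        return Tensor._make(out_data, (self,), backward)

    # -- backward pass ---------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (per-layer chains)
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

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                parent_grads = node._backward(g)
                for p, pg in zip(node._parents, parent_grads):
                    if not p.requires_grad or pg is None:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg
            else:
                if node.grad is None:
                    node.grad = g.astype(node.dtype, copy=True)
                else:
                    node.grad = node.grad + g.astype(node.dtype)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)
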