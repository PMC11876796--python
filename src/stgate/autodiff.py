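"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model in this package needs gradients through attention, gating and MLP
operations.  This module provides a small tensor type that records a dynamic
computation graph and back-propagates through it.  Only the operations the
model actually uses are implemented; everything is float64 and numpy-backed.

Gradient conventions
--------------------
* ``Tensor.grad`` accumulates ``d(loss)/d(tensor)`` with the same shape as
  ``tensor.data``.
* Binary operations support numpy broadcasting; gradients are summed back
  over broadcast axes.
* ``backward()`` may only be called on a scalar tensor.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concatenate",
    "maximum_scalar",
    "segment_sum",
    "as_tensor",
    "tune_allocator",
]

_ALLOCATOR_TUNED = False


def tune_allocator() -> None:
    """Ask glibc to keep large blocks on the heap instead of mmap'ing them.

    The training loop allocates and frees tens-of-MB activation buffers every
    step; with the default mmap threshold each one is returned to the kernel
    immediately and re-faulted on the next step.  No-op on non-glibc systems.
    """
    global _ALLOCATOR_TUNED
    if _ALLOCATOR_TUNED:
        return
    _ALLOCATOR_TUNED = True
    try:
        import ctypes
        libc = ctypes.CDLL("libc.so.6", use_errno=True)
        libc.mallopt(-3, 1 << 30)   # M_MMAP_THRESHOLD
        libc.mallopt(-4, 0)         # M_MMAP_MAX
    except Exception:
        pass


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading added axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "name", "_grad_alias")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str | None = None):
        data = np.asarray(data)
        if data.dtype != np.float32 and data.dtype != np.float64:
            data = data.astype(np.float64)  # ints/bools promote; floats pass
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None
        self.name = name
        self._grad_alias = False

    # ------------------------------------------------------------------ infra
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

    def _accum(self, g: np.ndarray):
        # first accumulation aliases the incoming array (never mutated);
        # a second accumulation materializes an owned buffer
        if self.grad is None:
            self.grad = g
            self._grad_alias = True
        elif self._grad_alias:
            self.grad = self.grad + g
            self._grad_alias = False
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        if isinstance(other, (int, float)):  # keeps float32 chains float32
            out = Tensor(self.data + other, parents=(self,))

            def bw_s(g):
                self._accum(g)
            out._backward = bw_s if out.requires_grad else None
            return out
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bw(g):
            self._accum(-g)
        out._backward = bw if out.requires_grad else None
        return out

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data * other, parents=(self,))

            def bw_s(g):
                self._accum(g * other)
            out._backward = bw_s if out.requires_grad else None
            return out
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2,
                                          other.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))
        out._backward = bw if out.requires_grad else None
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    # ----------------------------------------------------------- elementwise
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))

        def bw(g):
            self._accum(g * val)
        out._backward = bw if out.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g):
            self._accum(g / self.data)
        out._backward = bw if out.requires_grad else None
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, parents=(self,))

        def bw(g):
            self._accum(g * val * (1.0 - val))
        out._backward = bw if out.requires_grad else None
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))

        def bw(g):
            self._accum(g * mask)
        out._backward = bw if out.requires_grad else None
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), parents=(self,))

        def bw(g):
            self._accum(g * sign)
        out._backward = bw if out.requires_grad else None
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, parents=(self,))

        def bw(g):
            self._accum(g * 0.5 / val)
        out._backward = bw if out.requires_grad else None
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy()
                            if np.ndim(g) else np.full_like(self.data, g))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bw(g):
            self._accum(g.reshape(orig))
        out._backward = bw if out.requires_grad else None
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def bw(g):
            self._accum(g.transpose(inv))
        out._backward = bw if out.requires_grad else None
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), parents=(self,))

        def bw(g):
            self._accum(np.swapaxes(g, a, b))
        out._backward = bw if out.requires_grad else None
        return out

    def expand_dims(self, axis: int):
        out = Tensor(np.expand_dims(self.data, axis), parents=(self,))

        def bw(g):
            self._accum(np.squeeze(g, axis=axis))
        out._backward = bw if out.requires_grad else None
        return out

    def take(self, indices, axis: int):
        """Gather along ``axis`` with an integer index array."""
        indices = np.asarray(indices)
        out = Tensor(np.take(self.data, indices, axis=axis), parents=(self,))

        def bw(g):
            # scatter-add the gradient back to the gathered positions
            gi = np.zeros_like(self.data)
            idx = [slice(None)] * self.data.ndim
            if indices.ndim == 1:  # sort + reduceat beats unbuffered add.at
                order = np.argsort(indices, kind="stable")
                gs = np.take(g, order, axis=axis)
                uniq, starts = np.unique(indices[order], return_index=True)
                red = np.add.reduceat(gs, starts, axis=axis)
                gi[tuple(idx[:axis]) + (uniq,)] = red
            else:
                np.add.at(gi, tuple(idx[:axis]) + (indices,), g)
            self._accum(gi)
        out._backward = bw if out.requires_grad else None
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        pieces = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(p)
    out._backward = bw if out.requires_grad else None
    return out


def maximum_scalar(t: Tensor, floor: float) -> Tensor:
    """Elementwise max(t, floor); gradient flows only where t > floor."""
    mask = t.data > floor
    out = Tensor(np.maximum(t.data, floor), parents=(t,))

    def bw(g):
        t._accum(g * mask)
    out._backward = bw if out.requires_grad else None
    return out


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int,
                axis: int) -> Tensor:
    """Sum slices of ``t`` along ``axis`` into ``num_segments`` buckets.

    The inverse of ``take``: output[..., s, ...] = Σ_{e: ids[e]=s} t[..., e, ...].
    """
    segment_ids = np.asarray(segment_ids)
    shape = list(t.data.shape)
    shape[axis] = num_segments
    idx = [slice(None)] * t.data.ndim
    if segment_ids.size and np.all(np.diff(segment_ids) >= 0):
        # sorted ids: vectorized reduceat over the nonempty segments
        counts = np.bincount(segment_ids, minlength=num_segments)
        nonempty = np.flatnonzero(counts)
        starts = np.searchsorted(segment_ids, nonempty)
        red = np.add.reduceat(t.data, starts, axis=axis)
        val = np.zeros(shape, dtype=t.data.dtype)
        val[tuple(idx[:axis]) + (nonempty,)] = red
    else:
        val = np.zeros(shape, dtype=t.data.dtype)
        np.add.at(val, tuple(idx[:axis]) + (segment_ids,), t.data)
    out = Tensor(val, parents=(t,))

    def bw(g):
        t._accum(np.take(g, segment_ids, axis=axis))
    out._backward = bw if out.requires_grad else None
    return out
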