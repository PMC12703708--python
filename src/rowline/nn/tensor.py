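"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape-based autodiff core: a :class:`Tensor` wraps an
``ndarray`` and records the operations that produced it; ``backward()`` walks
the tape in reverse topological order and accumulates gradients.  Only the
operations the row-detection network needs are provided.  All operations
support NumPy-style broadcasting; gradients of broadcast operands are summed
back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast from `shape`."""
    if grad.shape == shape:
        return grad
    # leading added axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were expanded
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(p for p in parents if p.requires_grad)
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ meta
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

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def astype(self, dtype) -> "Tensor":
        out = Tensor(self.data.astype(dtype), parents=(self,))
        if out.requires_grad:
            def bw(g, self=self):
                self._accum(g.astype(self.data.dtype))
            out._backward = bw
        return out

    # -------------------------------------------------------------- backward
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            dt = np.result_type(self.data.dtype, np.float32)
            if g.shape == self.data.shape:
                self.grad = g.astype(dt, copy=True)
            else:
                self.grad = np.zeros(self.data.shape, dtype=dt)
                self.grad += g
        else:
            self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this tensor (must be scalar if grad is None)."""
        topo, seen = [], set()
        stack = [self]
        while stack:
            t = stack[-1]
            if id(t) in seen:
                stack.pop()
                continue
            # iterative DFS, post-order
            todo = [p for p in t._parents if id(p) not in seen]
            if todo:
                stack.extend(todo)
            else:
                seen.add(id(t))
                topo.append(t)
                stack.pop()
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data, dtype=np.float64 if self.data.dtype == np.float64 else np.float32)
        self._accum(np.asarray(grad))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(_unbroadcast(g, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(g, b.data.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(_unbroadcast(g * b.data, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(g * a.data, b.data.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(_unbroadcast(g / b.data, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, p=p: a._accum(g * p * a.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    ga = g @ np.swapaxes(b.data, -1, -2) if b.data.ndim > 1 else np.outer(g, b.data).reshape(a.data.shape)
                    a._accum(_unbroadcast(ga, a.data.shape))
                if b.requires_grad:
                    gb = np.swapaxes(a.data, -1, -2) @ g if a.data.ndim > 1 else np.outer(a.data, g).reshape(b.data.shape)
                    b._accum(_unbroadcast(gb, b.data.shape))
            out._backward = bw
        return out

    # ----------------------------------------------------------- elementwise
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, y=y: a._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g / a.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, y=y: a._accum(g * 0.5 / y)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g * np.sign(a.data))
        return out

    def tan(self):
        y = np.tan(self.data)
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, y=y: a._accum(g * (1.0 + y * y))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, m=mask: a._accum(g * m)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, y=y: a._accum(g * y * (1.0 - y))
        return out

    def clip(self, lo, hi):
        """Clamp; gradient passes through only where the value was not clipped."""
        mask = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, m=mask: a._accum(g * m)
        return out

    def clip_st(self, lo, hi):
        """Straight-through clamp: forward clips, backward passes gradients
        unchanged, so a value pushed against a bound can still be pulled back."""
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g)
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        if out.requires_grad:
            def bw(g, a=self, axis=axis, keepdims=keepdims):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.data.shape).copy() if g.shape != a.data.shape else g)
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ------------------------------------------------------------- structure
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g.reshape(a.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, inv=tuple(inv): a._accum(g.transpose(inv))
        return out

    @property
    def T(self):
        return self.transpose(tuple(range(self.ndim))[::-1])

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))
        if out.requires_grad:
            def bw(g, a=self, idx=idx):
                full = np.zeros_like(a.data, dtype=g.dtype)
                np.add.at(full, idx, g)
                a._accum(full)
            out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bw(g, tensors=tensors, offsets=offsets, axis=axis):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])
        out._backward = bw
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    if out.requires_grad:
        def bw(g, tensors=tensors, axis=axis):
            parts = np.moveaxis(g, axis, 0)
            for t, gp in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(gp)
        out._backward = bw
    return out
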