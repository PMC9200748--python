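"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine exists to train the U-Net generator and the Wasserstein patch
critic.  It is deliberately small: the only primitives are the ones those
networks need (elementwise arithmetic, matmul, reshape/transpose, im2col
``unfold``/``fold``, axis reductions, rectifiers).  Every primitive's
backward rule is itself expressed with these primitives, so gradients of
gradients work — that is what the critic's gradient penalty requires
(differentiating ‖∇_x D(x)‖ with respect to the critic weights).

Conventions follow the obvious reference points in the field: ``Tensor``
wraps a ``numpy`` array, ``backward()`` accumulates into ``.grad``, and
``grad(out, inputs, create_graph=True)`` returns gradients as new graph
nodes without touching ``.grad``.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    """Disable graph recording inside the block."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _recording() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad: "Tensor | None" = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None  # callable(out_grad: Tensor) -> tuple[Tensor|None]

    # -- introspection ---------------------------------------------------
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

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph construction ----------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _recording() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- autodiff core ----------------------------------------------------
    def backward(self, grad: "Tensor | None" = None, create_graph: bool = False):
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = Tensor(np.ones_like(self.data))
        gmap = _compute_grads(self, grad, create_graph)
        for node, g in gmap.items():
            if node._parents:
                continue  # only leaves keep .grad
            if node.grad is None:
                node.grad = g if create_graph else Tensor(g.data)
            else:
                acc = add(node.grad, g) if create_graph else Tensor(node.grad.data + g.data)
                node.grad = acc

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(_as_tensor(other)))

    def __rsub__(self, other):
        return add(_as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _compute_grads(out: Tensor, seed: Tensor, create_graph: bool) -> dict:
    """Reverse-topological gradient accumulation.

    Returns a dict mapping visited leaves (and the output) that require grad
    to their gradient Tensor.  Intermediate gradients are dropped as soon as
    they have been consumed, keeping peak memory proportional to the widest
    layer rather than the whole graph.  With ``create_graph`` the returned
    gradients are themselves differentiable graph nodes.
    """
    topo: list[Tensor] = []
    seen = set()

    def visit(node: Tensor):
        stack = [(node, False)]
        while stack:
            n, processed = stack.pop()
            if processed:
                topo.append(n)
                continue
            if id(n) in seen or not n.requires_grad:
                continue
            seen.add(id(n))
            stack.append((n, True))
            for p in n._parents:
                stack.append((p, False))

    visit(out)
    gmap: dict = {}
    gmap[id(out)] = (out, seed)
    _GRAD_ENABLED.append(create_graph)
    try:
        for node in reversed(topo):
            entry = gmap.get(id(node))
            if entry is None or node._backward is None:
                continue
            _, g = entry
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                prev = gmap.get(id(p))
                if prev is None:
                    gmap[id(p)] = (p, pg)
                else:
                    gmap[id(p)] = (p, add(prev[1], pg))
            if node._parents:
                del gmap[id(node)]  # consumed; free the buffer
    finally:
        _GRAD_ENABLED.pop()
    return {node: g for node, g in gmap.values()}


def grad(out: Tensor, inputs, create_graph: bool = False):
    """Gradients of scalar ``out`` w.r.t. ``inputs``, without touching ``.grad``."""
    if out.size != 1:
        raise ValueError("grad() requires a scalar output")
    seed = Tensor(np.ones_like(out.data))
    gmap = _compute_grads(out, seed, create_graph)
    return [gmap.get(i) for i in inputs]


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _sum_to(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a broadcasted gradient back to ``shape``."""
    if g.shape == shape:
        return g
    # sum leading extra axes
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    # sum broadcasted axes of size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        return _sum_to(g, a.shape), _sum_to(g, b.shape)

    return Tensor._make(a.data + b.data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    def backward(g):
        return (neg(g),)

    return Tensor._make(-a.data, (a,), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        return _sum_to(mul(g, b), a.shape), _sum_to(mul(g, a), b.shape)

    return Tensor._make(a.data * b.data, (a, b), backward)


def power(a: Tensor, p: float) -> Tensor:
    def backward(g):
        return (mul(g, mul(Tensor(np.asarray(p, dtype=a.dtype)), power(a, p - 1.0))),)

    return Tensor._make(a.data ** p, (a,), backward)


def absolute(a: Tensor) -> Tensor:
    sign = np.sign(a.data)

    def backward(g):
        return (mul(g, Tensor(sign)),)

    return Tensor._make(np.abs(a.data), (a,), backward)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        gd = g
        if not keepdims and axis is not None:
            axes = axis if isinstance(axis, tuple) else (axis,)
            shape = list(g.shape)
            for ax in sorted(a_ % a.ndim for a_ in axes):
                shape.insert(ax, 1)
            gd = reshape(g, tuple(shape))
        elif axis is None and not keepdims:
            gd = reshape(g, (1,) * a.ndim)
        return (broadcast_to(gd, a.shape),)

    return Tensor._make(out_data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(np.asarray(1.0 / n, dtype=a.dtype)))


def broadcast_to(a: Tensor, shape: tuple) -> Tensor:
    def backward(g):
        return (_sum_to(g, a.shape),)

    return Tensor._make(np.broadcast_to(a.data, shape), (a,), backward)


def reshape(a: Tensor, shape: tuple) -> Tensor:
    orig = a.shape

    def backward(g):
        return (reshape(g, orig),)

    return Tensor._make(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes: tuple) -> Tensor:
    inv = tuple(np.argsort(axes))

    def backward(g):
        return (transpose(g, inv),)

    return Tensor._make(a.data.transpose(axes), (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product; backward is two matrix products."""
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")

    def backward(g):
        ga = matmul(g, transpose(b, (1, 0)))
        gb = matmul(transpose(a, (1, 0)), g)
        return ga, gb

    return Tensor._make(a.data @ b.data, (a, b), backward)


def concat(tensors, axis: int) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        grads = []
        for i in range(len(tensors)):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            grads.append(narrow(g, tuple(sl)))
        return tuple(grads)

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def narrow(a: Tensor, slices: tuple) -> Tensor:
    shape = a.shape

    def backward(g):
        def scatter(gg):
            buf = np.zeros(shape, dtype=gg.dtype)
            buf[slices] = gg.data
            # linear op: backward of scatter is slicing again
            def back2(g2):
                return (narrow(g2, slices),)

            return Tensor._make(buf, (gg,), back2)

        return (scatter(g),)

    return Tensor._make(a.data[slices], (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = (a.data > 0).astype(a.dtype)

    def backward(g):
        return (mul(g, Tensor(mask)),)

    return Tensor._make(a.data * mask, (a,), backward)


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    factor = np.where(a.data > 0, np.asarray(1.0, a.dtype), np.asarray(slope, a.dtype))

    def backward(g):
        return (mul(g, Tensor(factor)),)

    return Tensor._make(a.data * factor, (a,), backward)


def tmax(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    out_data = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == out_data).astype(a.dtype)
    counts = mask.sum(axis=axis, keepdims=True)
    mask /= counts  # split ties evenly so the map stays linear in g

    def backward(g):
        gd = g
        if not keepdims:
            shape = list(g.shape)
            shape.insert(axis % a.ndim, 1)
            gd = reshape(g, tuple(shape))
        return (mul(broadcast_to(gd, a.shape), Tensor(mask)),)

    out = out_data if keepdims else out_data.squeeze(axis=axis)
    return Tensor._make(out, (a,), backward)


def sqrt(a: Tensor) -> Tensor:
    return power(a, 0.5)


# -- im2col / col2im ---------------------------------------------------------

def _unfold_data(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (H + 2 * pad - k) // stride + 1
    ow = (W + 2 * pad - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]  # (B, C, oh, ow, k, k)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(B, oh * ow, C * k * k)
    return cols


def _fold_data(cols: np.ndarray, out_hw: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    B = cols.shape[0]
    H, W = out_hw
    C = cols.shape[2] // (k * k)
    oh = (H + 2 * pad - k) // stride + 1
    ow = (W + 2 * pad - k) // stride + 1
    cols6 = cols.reshape(B, oh, ow, C, k, k)
    buf = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    for ki in range(k):
        for kj in range(k):
            buf[:, :, ki:ki + stride * oh:stride, kj:kj + stride * ow:stride] += cols6[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
    if pad:
        buf = buf[:, :, pad:H + pad, pad:W + pad]
    return buf


def unfold(x: Tensor, k: int, stride: int = 1, pad: int = 0) -> Tensor:
    """im2col: (B, C, H, W) -> (B, L, C·k·k) sliding-window columns."""
    hw = x.shape[2:]

    def backward(g):
        return (fold(g, hw, k, stride, pad),)

    return Tensor._make(_unfold_data(x.data, k, stride, pad), (x,), backward)


def fold(cols: Tensor, out_hw: tuple, k: int, stride: int = 1, pad: int = 0) -> Tensor:
    """col2im scatter-add, the linear adjoint of :func:`unfold`."""

    def backward(g):
        return (unfold(g, k, stride, pad),)

    return Tensor._make(_fold_data(cols.data, out_hw, k, stride, pad), (cols,), backward)
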