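"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sufficient for the encoder/decoder/predictor
networks in this package: broadcast-aware elementwise ops, (batched)
matmul, softmax, log-sum-exp building blocks, gather, and an Adam
optimizer. Gradients are plain ``np.ndarray``s accumulated on leaves.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph plumbing -------------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        topo, seen = [], set()
        stack = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    acc = grads.get(id(parent))
                    grads[id(parent)] = pg if acc is None else acc + pg
            else:  # leaf
                node.grad = g if node.grad is None else node.grad + g

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        def bw(g):
            return ((self, _unbroadcast(g, self.shape)),
                    (other, _unbroadcast(g, other.shape)))
        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        def bw(g):
            return ((self, _unbroadcast(g * other.data, self.shape)),
                    (other, _unbroadcast(g * self.data, other.shape)))
        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        def bw(g):
            return ((self, _unbroadcast(g / other.data, self.shape)),
                    (other, _unbroadcast(-g * self.data / other.data ** 2,
                                         other.shape)))
        return self._make(self.data / other.data, (self, other), bw)

    def __matmul__(self, other):
        other = self._wrap(other)
        def bw(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                a2 = a[None, :]
                ga = (g[..., None, :] @ np.swapaxes(b, -1, -2))[..., 0, :]
                gb = np.swapaxes(a2, -1, -2) @ g[..., None, :]
            elif b.ndim == 1:
                ga = g[..., :, None] @ b[None, :]
                gb = np.swapaxes(a, -1, -2) @ g[..., :, None]
                gb = gb[..., 0]
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            return ((self, _unbroadcast(ga, self.shape)),
                    (other, _unbroadcast(gb, other.shape)))
        return self._make(self.data @ other.data, (self, other), bw)

    # -- nonlinearities -------------------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)
        def bw(g):
            return ((self, g * (1.0 - out_data ** 2)),)
        return self._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: ((self, g * mask),))

    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: ((self, g * out_data),))

    def log(self):
        return self._make(np.log(self.data), (self,),
                          lambda g: ((self, g / self.data),))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,),
                          lambda g: ((self, g * 0.5 / out_data),))

    # -- reductions / reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                return ((self, np.broadcast_to(g, self.shape).copy()),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return ((self, np.broadcast_to(g, self.shape).copy()),)
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return self._make(self.data.reshape(shape), (self,),
                          lambda g: ((self, g.reshape(old)),))

    def swapaxes(self, a, b):
        return self._make(np.swapaxes(self.data, a, b), (self,),
                          lambda g: ((self, np.swapaxes(g, a, b)),))

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def take_flat(self, flat_idx: np.ndarray):
        """Gather elements by flat index; backward scatter-adds."""
        flat_idx = np.asarray(flat_idx)
        def bw(g):
            full = np.zeros(self.data.size)
            np.add.at(full, flat_idx.ravel(), np.asarray(g).ravel())
            return ((self, full.reshape(self.shape)),)
        return self._make(self.data.ravel()[flat_idx], (self,), bw)

    def __getitem__(self, key):
        """Basic (slice/int) indexing with scatter-add backward."""
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return ((self, full),)
        return self._make(self.data[key], (self,), bw)

    def take_rows(self, idx: np.ndarray):
        idx = np.asarray(idx)
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((self, full),)
        return self._make(self.data[idx], (self,), bw)


def concat(tensors, axis=0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bw(g):
        out = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            out.append((t, g[tuple(sl)]))
        return tuple(out)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = bw
    return out


def softmax(x: Tensor, axis=-1) -> Tensor:
    """Numerically stable softmax as a primitive (efficient backward)."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    # clip far-below-max entries (e.g. additive masks): avoids slow
    # subnormal exp while leaving relative mass < 1e-300
    e = np.exp(np.maximum(shifted, -700.0))
    out_data = e / e.sum(axis=axis, keepdims=True)
    def bw(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        return ((x, out_data * (g - dot)),)
    out = Tensor(out_data)
    out.requires_grad = x.requires_grad
    if out.requires_grad:
        out._parents = (x,)
        out._backward = bw
    return out


class Adam:
    """Adam optimizer over a list of leaf Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
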