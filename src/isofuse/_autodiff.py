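"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the model needs: dense affine maps,
elementwise nonlinearities, reductions, row indexing and segment-wise max
pooling (the multiple-instance "best isoform" primitive). Gradients are
accumulated by topological traversal of the tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "segment_max_matrix"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, self.requires_grad)
        out._parents = (self,)

        def bw(g):
            return (g.T,)

        out._backward = bw
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad)
        out._parents = (self, other)
        out._backward = lambda g: (
            _unbroadcast(g, self.data.shape),
            _unbroadcast(g, other.data.shape),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad)
        out._parents = (self, other)
        out._backward = lambda g: (
            _unbroadcast(g * other.data, self.data.shape),
            _unbroadcast(g * self.data, other.data.shape),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, self.requires_grad or other.requires_grad)
        out._parents = (self, other)
        out._backward = lambda g: (
            _unbroadcast(g / other.data, self.data.shape),
            _unbroadcast(-g * self.data / other.data**2, other.data.shape),
        )
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, self.requires_grad or other.requires_grad)
        out._parents = (self, other)
        out._backward = lambda g: (g @ other.data.T, self.data.T @ g)
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    # -- elementwise nonlinearities --------------------------------------
    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: (g / self.data,)
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: (g * out.data,)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, slope * self.data), self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: (g * np.where(mask, 1.0, slope),)
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: (g * sign,)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through unclipped entries only."""
        mask = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: (g * mask,)
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None):
        out = Tensor(self.data.sum(axis=axis), self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if axis is None:
                return (np.full_like(self.data, 1.0) * g,)
            return (np.broadcast_to(np.expand_dims(g, axis), self.data.shape).copy(),)

        out._backward = bw
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    # -- structural ops --------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def take_rows(self, idx):
        """Row subset; gradient scatters back."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], self.requires_grad)
        out._parents = (self,)

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = bw
        return out

    def segment_max(self, seg_ids, n_seg: int):
        """Max-pool rows by segment: out[s] = max over rows i with seg_ids[i]==s.

        Gradient flows only to the (first) argmax row per segment and column —
        the standard subgradient for a hard max.
        """
        seg_ids = np.asarray(seg_ids, dtype=np.intp)
        n_cols = self.data.shape[1]
        out_data = np.full((n_seg, n_cols), -np.inf)
        np.maximum.at(out_data, seg_ids, self.data)
        # argmax rows per (segment, column) for the backward scatter
        arg = np.zeros((n_seg, n_cols), dtype=np.intp)
        hit = self.data == out_data[seg_ids]  # rows achieving the segment max
        # first achiever wins: iterate rows in reverse so earliest overwrites last
        for i in range(self.data.shape[0] - 1, -1, -1):
            cols = np.nonzero(hit[i])[0]
            arg[seg_ids[i], cols] = i
        out = Tensor(out_data, self.requires_grad)
        out._parents = (self,)

        def bw(g):
            # scatter: full[arg[s, c], c] += g[s, c]
            full = np.zeros_like(self.data)
            rows = arg.ravel()
            ccols = np.tile(np.arange(n_cols), n_seg)
            np.add.at(full, (rows, ccols), g.ravel())
            return (full,)

        out._backward = bw
        return out

    # -- backward --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and t._backward is None:  # leaf parameter
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if not (p.requires_grad or p._parents):
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


class Parameter(Tensor):
    """A leaf tensor tracked by an optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)

    def zero_grad(self):
        self.grad = None


def segment_max_matrix(x: np.ndarray, seg_ids, n_seg: int) -> np.ndarray:
    """Plain-NumPy segment max over rows (no tape)."""
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    out = np.full((n_seg, x.shape[1]), -np.inf)
    np.maximum.at(out, seg_ids, x)
    return out


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
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
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
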