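"""Compact reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the gene-cell graph transformer needs:
dense matmul, broadcast add/mul/div, reshape, reductions, exp/log/softplus,
row-wise layer normalization, and multiplication by a constant sparse matrix
(used for edge gather and segment-sum scatter on the bipartite graph).

Gradients are accumulated by topological traversal of the recorded tape.
Correctness is established against central finite differences in the test
suite; the engine is intentionally minimal and CPU-only.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as _sp


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal ---------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        g = g.astype(np.float32, copy=False)
        self.grad = g if self.grad is None else self.grad + g

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (_as_tensor(other) * (-1.0))

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bwd
        return out

    __radd__ = __add__
    __rmul__ = __mul__

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bwd
        return out

    def transpose(self):
        out = Tensor(self.data.T, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.T)

        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * val)

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bwd
        return out

    def softplus(self):
        # numerically stable: log1p(exp(-|x|)) + max(x, 0)
        x = self.data
        val = np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)
        out = Tensor(val, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                # overflow-safe logistic
                sig = np.empty_like(x)
                pos = x >= 0
                sig[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
                ex = np.exp(x[~pos])
                sig[~pos] = ex / (1.0 + ex)
                self._accum(g * sig)

        out._backward = bwd
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def constant(x) -> Tensor:
    return _as_tensor(x)


def parameter(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float32), requires_grad=True)


def spmm(mat: _sp.spmatrix, t: Tensor) -> Tensor:
    """Multiply a constant sparse matrix by a 2-D tensor: out = mat @ t.

    Backprop uses the transpose; used for gathering node rows onto edges
    (one-hot rows) and scattering edge messages back onto nodes.
    """
    mat = mat.tocsr()
    out = Tensor(mat @ t.data, parents=(t,))
    mat_t = mat.T.tocsr()

    def bwd(g):
        if t.requires_grad:
            t._accum(mat_t @ g)

    out._backward = bwd
    return out


def layer_norm(t: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Row-wise layer normalization with learnable affine parameters."""
    x = t.data
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gain.data + bias.data, parents=(t, gain, bias))
    d = x.shape[-1]

    def bwd(g):
        if gain.requires_grad:
            gain._accum(_unbroadcast(g * xhat, gain.data.shape))
        if bias.requires_grad:
            bias._accum(_unbroadcast(g, bias.data.shape))
        if t.requires_grad:
            gxhat = g * gain.data
            # standard layer-norm backward
            term1 = gxhat
            term2 = gxhat.mean(axis=-1, keepdims=True)
            term3 = xhat * (gxhat * xhat).mean(axis=-1, keepdims=True)
            t._accum(inv * (term1 - term2 - term3))
        _ = d  # noqa: F841

    out._backward = bwd
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=0.01, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
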