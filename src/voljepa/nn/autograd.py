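"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operator set the package's transformer encoder,
predictor and probe heads need: broadcasting arithmetic, batched matmul,
softmax, GELU, layer-norm building blocks, indexing/reshaping, smooth-L1 and
weighted binary cross-entropy. Gradients accumulate into ``Tensor.grad`` via
``backward()`` over a topologically sorted tape.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concatenate", "smooth_l1", "weighted_bce_logits"]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 100  # so ndarray + Tensor defers to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, prev, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(prev)
            out._backward = backward
        return out

    def _accum(self, grad):
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        o = self._wrap(other)
        out = self._make(self.data + o.data, (self, o), None)

        def bw():
            if self.requires_grad:
                self._accum(out.grad)
            if o.requires_grad:
                o._accum(out.grad)
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)

        def bw():
            self._accum(-out.grad)
        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        o = self._wrap(other)
        out = self._make(self.data * o.data, (self, o), None)

        def bw():
            if self.requires_grad:
                self._accum(out.grad * o.data)
            if o.requires_grad:
                o._accum(out.grad * self.data)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        out = self._make(self.data ** p, (self,), None)

        def bw():
            self._accum(out.grad * p * self.data ** (p - 1))
        out._backward = bw
        return out

    def __matmul__(self, other):
        o = self._wrap(other)
        out = self._make(self.data @ o.data, (self, o), None)

        def bw():
            if self.requires_grad:
                self._accum(out.grad @ np.swapaxes(o.data, -1, -2))
            if o.requires_grad:
                o._accum(np.swapaxes(self.data, -1, -2) @ out.grad)
        out._backward = bw
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        e = np.exp(self.data)
        out = self._make(e, (self,), None)

        def bw():
            self._accum(out.grad * e)
        out._backward = bw
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)

        def bw():
            self._accum(out.grad / self.data)
        out._backward = bw
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = self._make(t, (self,), None)

        def bw():
            self._accum(out.grad * (1 - t * t))
        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = self._make(s, (self,), None)

        def bw():
            self._accum(out.grad * s * (1 - s))
        out._backward = bw
        return out

    def gelu(self):
        """Exact GELU, x·Φ(x)."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x * _INV_SQRT2))
        out = self._make(x * phi, (self,), None)

        def bw():
            dens = np.exp(-0.5 * x * x) * _INV_SQRT2PI
            self._accum(out.grad * (phi + x * dens))
        out._backward = bw
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = self._make(s, (self,), None)

        def bw():
            g = out.grad
            self._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))
        out._backward = bw
        return out

    # -- reductions & shaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims),
                         (self,), None)

        def bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,), None)

        def bw():
            self._accum(out.grad.reshape(self.data.shape))
        out._backward = bw
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = self._make(self.data.transpose(axes), (self,), None)

        def bw():
            self._accum(out.grad.transpose(inv))
        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)

        def bw():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)
        out._backward = bw
        return out


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def bw():
            for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
                if t.requires_grad or t._prev:
                    t._accum(g)
        out._backward = bw
    return out


def smooth_l1(pred: Tensor, target: Tensor, beta: float = 1.0) -> Tensor:
    """Elementwise smooth-L1 (Huber-style): quadratic 0.5·d²/β for |d| < β,
    linear |d| − 0.5β otherwise. Returns the mean over all elements."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    d = pred.data - target.data
    ad = np.abs(d)
    val = np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)
    out = Tensor(val.mean())
    if pred.requires_grad or pred._prev or target.requires_grad or target._prev:
        out.requires_grad = True
        out._prev = (pred, target)

        def bw():
            g = out.grad * np.where(ad < beta, d / beta, np.sign(d)) / d.size
            if pred.requires_grad or pred._prev:
                pred._accum(g)
            if target.requires_grad or target._prev:
                target._accum(-g)
        out._backward = bw
    return out


def weighted_bce_logits(logits: Tensor, labels: np.ndarray,
                        pos_weight: np.ndarray | float = 1.0) -> Tensor:
    """Mean class-weighted binary cross-entropy on logits.

    Per element: w·(softplus(z) − z·y) with w = pos_weight for positives and
    1 for negatives; numerically stable for large |z|.
    """
    y = np.asarray(labels, dtype=np.float64)
    w = y * np.asarray(pos_weight, dtype=np.float64) + (1.0 - y)
    z = logits.data
    softplus = np.maximum(z, 0) + np.log1p(np.exp(-np.abs(z)))
    out = Tensor((w * (softplus - z * y)).mean())
    if logits.requires_grad or logits._prev:
        out.requires_grad = True
        out._prev = (logits,)

        def bw():
            sig = 1.0 / (1.0 + np.exp(-z))
            logits._accum(out.grad * w * (sig - y) / z.size)
        out._backward = bw
    return out
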