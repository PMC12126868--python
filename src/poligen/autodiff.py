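"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the equivariant message-passing networks
need: broadcasting arithmetic, matmul, reductions, row gather / segment-sum
(the scatter primitive of graph message passing), concatenation, slicing and
smooth nonlinearities.  Everything runs in float64.

Gradient graphs are ordinary Python object graphs; call :meth:`Tensor.backward`
on a scalar to populate ``.grad`` on every reachable tensor that has
``requires_grad`` set.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "segment_sum", "softmax", "log_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("pass Tensor through ops, not _as_array")
    return np.asarray(x, dtype=np.float64)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = data if isinstance(data, np.ndarray) and data.dtype == np.float64 \
            else np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(_as_array(x))

    def _make(self, data, parents, backward) -> "Tensor":
        rg = any(p.requires_grad or p._parents for p in parents)
        return Tensor(data, requires_grad=False, parents=parents if rg else (),
                      backward=backward if rg else None)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def bw(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def bw(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def bw(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return self._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            return (g * p * self.data ** (p - 1),)

        return self._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def bw(g):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(out_data, (self, other), bw)

    # -- elementwise functions -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,), lambda g: (g * (1.0 - out_data ** 2),))

    def sigmoid(self):
        from scipy.special import expit
        out_data = expit(self.data)
        return self._make(out_data, (self,),
                          lambda g: (g * out_data * (1.0 - out_data),))

    def silu(self):
        from scipy.special import expit
        s = expit(self.data)
        out_data = self.data * s

        def bw(g):
            return (g * (s * (1.0 + self.data * (1.0 - s))),)

        return self._make(out_data, (self,), bw)

    # -- reductions & shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        return self._make(out_data, (self,), lambda g: (g.reshape(self.shape),))

    @property
    def T(self):
        return self._make(self.data.T, (self,), lambda g: (g.T,))

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros(self.shape)
            np.add.at(full, idx, g)
            return (full,)

        return self._make(out_data, (self,), bw)

    # -- autodiff driver ---------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.ones_like(self.data)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# free functions


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        outs = []
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            outs.append(g[tuple(sl)])
        return tuple(outs)

    probe = Tensor(out_data)
    rg = any(t.requires_grad or t._parents for t in tensors)
    if rg:
        probe._parents = tuple(tensors)
        probe._backward = bw
    return probe


def segment_sum(values: Tensor, index: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``values`` into ``num_segments`` buckets given by ``index``.

    The aggregation primitive of message passing: messages on edges are summed
    onto their destination nodes.  Backward is a row gather.
    """
    index = np.asarray(index)
    out_data = np.zeros((num_segments,) + values.data.shape[1:])
    np.add.at(out_data, index, values.data)

    def bw(g):
        return (g[index],)

    out = Tensor(out_data)
    if values.requires_grad or values._parents:
        out._parents = (values,)
        out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, no grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    x0 = x - shift
    return x0 - x0.exp().sum(axis=axis, keepdims=True).log()
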