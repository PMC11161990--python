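"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the Transformer autoencoders in this package:
broadcast-aware elementwise arithmetic, batched matmul, reductions, a few
nonlinearities, embedding lookup, gather, slicing and zero-padding.  Graphs
are built eagerly; :meth:`Tensor.backward` runs a topological sweep and
accumulates gradients into ``.grad``.

Everything is float64 numpy under the hood, which keeps desk-scale training
bit-reproducible across runs with the same seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(),
                 backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph mechanics -----------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        requires = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=requires,
                      parents=parents if requires else (),
                      backward=backward if requires else None)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = np.zeros_like(node.data)
            node.grad = node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        return self._make(self.data + other.data, (self, other),
                          lambda g: (_unbroadcast(g, self.shape),
                                     _unbroadcast(g, other.shape)))

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return self._make(self.data * other.data, (self, other),
                          lambda g: (_unbroadcast(g * other.data, self.shape),
                                     _unbroadcast(g * self.data, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        data = self.data ** exponent
        return self._make(data, (self,),
                          lambda g: (g * exponent * self.data ** (exponent - 1.0),))

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            ga = _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape)
            gb = _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape)
            return ga, gb

        return self._make(self.data @ other.data, (self, other), backward)

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def tanh(self):
        out = np.tanh(self.data)
        return self._make(out, (self,), lambda g: (g * (1.0 - out ** 2),))

    def exp(self):
        out = np.exp(self.data)
        return self._make(out, (self,), lambda g: (g * out,))

    def log(self):
        return self._make(np.log(self.data), (self,),
                          lambda g: (g / self.data,))

    # -- reductions and shaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        return self._make(self.data.reshape(*shape), (self,),
                          lambda g: (g.reshape(self.shape),))

    def transpose(self, *axes):
        inverse = np.argsort(axes)
        return self._make(self.data.transpose(*axes), (self,),
                          lambda g: (g.transpose(*inverse),))

    def swap_last(self):
        return self._make(np.swapaxes(self.data, -1, -2), (self,),
                          lambda g: (np.swapaxes(g, -1, -2),))

    def __getitem__(self, key):
        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, key, g)
            return (out,)

        return self._make(self.data[key], (self,), backward)

    def pad_axis1(self, before: int, after: int):
        """Zero-pad along axis 1 (sequence axis of (B, L, C) activations)."""
        widths = [(0, 0)] * self.ndim
        widths[1] = (before, after)
        L = self.shape[1]
        return self._make(np.pad(self.data, widths), (self,),
                          lambda g: (g[:, before:before + L],))

    # -- softmax family ------------------------------------------------------
    def log_softmax(self, axis: int = -1):
        shift = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shift - shift.exp().sum(axis=axis, keepdims=True).log()

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    def gather_last(self, index: np.ndarray):
        """Pick one entry along the last axis per leading position."""
        index = np.asarray(index)
        picked = np.take_along_axis(self.data, index[..., None], axis=-1)[..., 0]

        def backward(g):
            out = np.zeros_like(self.data)
            np.put_along_axis(out, index[..., None], g[..., None], axis=-1)
            return (out,)

        return self._make(picked, (self,), backward)


def embedding_lookup(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add gradient."""
    ids = np.asarray(ids)

    def backward(g):
        gw = np.zeros_like(weight.data)
        np.add.at(gw, ids.reshape(-1),
                  g.reshape(-1, weight.data.shape[1]))
        return (gw,)

    return weight._make(weight.data[ids], (weight,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        slicer = [slice(None)] * g.ndim
        outs = []
        for k in range(len(tensors)):
            slicer[axis] = slice(offsets[k], offsets[k + 1])
            outs.append(g[tuple(slicer)])
        return tuple(outs)

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return tensors[0]._make(data, tuple(tensors), backward)
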