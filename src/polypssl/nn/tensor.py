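"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records, for each produced tensor,
the parent tensors and a closure that maps the output gradient to parent
gradients.  Calling :meth:`Tensor.backward` on a scalar runs the tape in
reverse topological order.  Only the operations needed by the segmentation
network live here and in :mod:`polypssl.nn.functional`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "no_grad", "grad_enabled"]

_GRAD_ENABLED = [True]


def grad_enabled() -> bool:
    return _GRAD_ENABLED[0]


class no_grad:
    """Context manager that disables tape construction (inference mode)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self.name = name

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            node._backward(node.grad)
            if node._parents:  # free intermediate grads eagerly
                node.grad = None

    # -- operators (thin wrappers over functional) -------------------------
    def __add__(self, other):
        from . import functional as F

        return F.add(self, as_tensor(other, self.dtype))

    __radd__ = __add__

    def __sub__(self, other):
        from . import functional as F

        return F.sub(self, as_tensor(other, self.dtype))

    def __rsub__(self, other):
        from . import functional as F

        return F.sub(as_tensor(other, self.dtype), self)

    def __mul__(self, other):
        from . import functional as F

        return F.mul(self, as_tensor(other, self.dtype))

    __rmul__ = __mul__

    def __neg__(self):
        from . import functional as F

        return F.mul(self, as_tensor(-1.0, self.dtype))

    def __pow__(self, k):
        from . import functional as F

        if k != 2:
            raise NotImplementedError("only squaring is supported")
        return F.square(self)

    def mean(self, axis=None):
        from . import functional as F

        return F.mean(self, axis=axis)

    def sum(self, axis=None):
        from . import functional as F

        return F.sum(self, axis=axis)

    def reshape(self, *shape):
        from . import functional as F

        return F.reshape(self, shape if len(shape) > 1 else shape[0])

    def __repr__(self):
        req = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}{req})"


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x, dtype=dtype)
    return Tensor(arr)
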