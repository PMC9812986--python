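"""Reverse-mode autodiff over numpy arrays.

A :class:`Tensor` wraps a float32 ``numpy.ndarray`` together with an optional
gradient buffer.  Operations (defined in :mod:`tubuleseg.nn.functional`) build a
DAG of tensors; :meth:`Tensor.backward` walks it in reverse topological order,
calling the per-op backward closures.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor"]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward_fn = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def accumulate_grad(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).copy()
        else:
            self.grad += g

    @staticmethod
    def result(data, parents: tuple["Tensor", ...], backward_fn) -> "Tensor":
        """Build an op output; gradient tracking follows the parents."""
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward_fn = backward_fn
        return out

    # --------------------------------------------------------------- backward
    def backward(self) -> None:
        """Backpropagate from this (typically scalar loss) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for big encoders
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

        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward_fn is not None and node.grad is not None:
                node._backward_fn(node.grad)
                # free intermediate grads/graph as we go
                node._backward_fn = None
                node._parents = ()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"
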