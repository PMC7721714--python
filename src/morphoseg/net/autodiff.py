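"""Minimal reverse-mode autodiff over numpy arrays.

Just enough machinery to express a pseudo-3D encoder-decoder and its loss:
a tape of nodes created in forward order, each holding a backward closure
that maps the output gradient to parent gradients. Layers own their
parameters and accumulate parameter gradients inside their backward
closures.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Node:
    """One tensor in the computation graph."""

    __slots__ = ("value", "parents", "bw", "grad")

    def __init__(self, value, parents=(), bw=None):
        self.value = value
        self.parents = parents
        self.bw = bw          # callable grad -> tuple of parent grads
        self.grad = None


class Tape:
    """Records nodes in forward order; backward walks them in reverse."""

    def __init__(self):
        self.nodes: list[Node] = []

    def node(self, value, parents=(), bw=None) -> Node:
        n = Node(value, parents, bw)
        self.nodes.append(n)
        return n

    def backward(self, loss_node: Node, seed: float = 1.0) -> None:
        for n in self.nodes:
            n.grad = None
        loss_node.grad = np.asarray(seed, dtype=np.float64)
        for n in reversed(self.nodes):
            if n.grad is None or n.bw is None:
                continue
            parent_grads = n.bw(n.grad)
            for p, g in zip(n.parents, parent_grads):
                if g is None:
                    continue
                if p.grad is None:
                    p.grad = g
                else:
                    p.grad = p.grad + g


class Adam:
    """Adam optimizer over a list of Params."""

    def __init__(self, params: list[Param], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
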