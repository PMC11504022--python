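"""First-order optimizers for the autograd tensors."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["SGD", "Adam", "clip_grad_norm"]


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    total = float(np.sqrt(sum(float((p.grad ** 2).sum()) for p in params if p.grad is not None)))
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total


class SGD:
    def __init__(self, params: list[Tensor], lr: float = 1e-2, momentum: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum = lr, momentum
        self.vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self.vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data = p.data - self.lr * v.astype(p.data.dtype)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data = p.data - (self.lr * update).astype(p.data.dtype)
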