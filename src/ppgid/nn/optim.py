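"""Gradient-descent optimizers over a flat parameter list."""

from __future__ import annotations

import numpy as np

from .core import Param

__all__ = ["SGD", "Adam", "RMSprop", "make_optimizer"]


class Optimizer:
    def __init__(self, params: list[Param], lr: float):
        self.params = params
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:  # pragma: no cover
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params: list[Param], lr: float = 0.01, momentum: float = 0.9):
        super().__init__(params, lr)
        self.momentum = momentum
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.v):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v


class Adam(Optimizer):
    def __init__(
        self,
        params: list[Param],
        lr: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        super().__init__(params, lr)
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


class RMSprop(Optimizer):
    def __init__(self, params: list[Param], lr: float = 0.001, rho: float = 0.9, eps: float = 1e-8):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.v):
            v *= self.rho
            v += (1 - self.rho) * p.grad**2
            p.value -= self.lr * p.grad / (np.sqrt(v) + self.eps)


def make_optimizer(name: str, params: list[Param], lr: float) -> Optimizer:
    table = {"sgd": SGD, "adam": Adam, "rmsprop": RMSprop}
    if name not in table:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(table)}")
    return table[name](params, lr=lr)
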