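"""Optimizers and learning-rate schedulers.

Covers the hyper-parameter grid used by the training harness: SGD with
momentum, Adam and RMSprop, plus step, multi-step, cosine-annealing,
reduce-on-plateau and cyclic schedules.
"""

from __future__ import annotations

import math

import numpy as np


class Optimizer:
    def __init__(self, params, lr: float):
        self.params = list(params)
        self.lr = float(lr)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr: float, momentum: float = 0.0):
        super().__init__(params, lr)
        self.momentum = momentum
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v


class Adam(Optimizer):
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, params, lr: float = 1e-3, alpha: float = 0.99,
                 eps: float = 1e-8, momentum: float = 0.0):
        super().__init__(params, lr)
        self.alpha, self.eps, self.momentum = alpha, eps, momentum
        self._sq = [np.zeros_like(p.data) for p in self.params]
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, sq, buf in zip(self.params, self._sq, self._buf):
            if p.grad is None:
                continue
            sq *= self.alpha
            sq += (1.0 - self.alpha) * p.grad ** 2
            upd = p.grad / (np.sqrt(sq) + self.eps)
            if self.momentum > 0:
                buf *= self.momentum
                buf += upd
                upd = buf
            p.data -= self.lr * upd


# ----------------------------------------------------------------------
# schedulers: step(metric) is called once per epoch; plateau schedules
# use the metric (validation loss), the others ignore it.

class Scheduler:
    def __init__(self, optimizer: Optimizer):
        self.optimizer = optimizer
        self.base_lr = optimizer.lr
        self.epoch = 0

    def step(self, metric: float | None = None) -> None:
        self.epoch += 1
        self.optimizer.lr = self._lr_at(self.epoch, metric)

    def _lr_at(self, epoch: int, metric):
        raise NotImplementedError


class StepLR(Scheduler):
    def __init__(self, optimizer, step_size: int = 30, gamma: float = 0.1):
        super().__init__(optimizer)
        self.step_size, self.gamma = step_size, gamma

    def _lr_at(self, epoch, metric):
        return self.base_lr * self.gamma ** (epoch // self.step_size)


class MultiStepLR(Scheduler):
    def __init__(self, optimizer, milestones=(30, 60, 90), gamma: float = 0.1):
        super().__init__(optimizer)
        self.milestones = sorted(milestones)
        self.gamma = gamma

    def _lr_at(self, epoch, metric):
        k = sum(1 for m in self.milestones if epoch >= m)
        return self.base_lr * self.gamma ** k


class CosineAnnealingLR(Scheduler):
    def __init__(self, optimizer, t_max: int = 100, eta_min: float = 0.0):
        super().__init__(optimizer)
        self.t_max, self.eta_min = t_max, eta_min

    def _lr_at(self, epoch, metric):
        t = min(epoch, self.t_max)
        return self.eta_min + 0.5 * (self.base_lr - self.eta_min) * (
            1.0 + math.cos(math.pi * t / self.t_max)
        )


class ReduceLROnPlateau(Scheduler):
    """Multiply the LR by ``factor`` when the metric stops improving."""

    def __init__(self, optimizer, factor: float = 0.1, patience: int = 10,
                 min_lr: float = 0.0):
        super().__init__(optimizer)
        self.factor, self.patience, self.min_lr = factor, patience, min_lr
        self.best = math.inf
        self.bad_epochs = 0

    def step(self, metric: float | None = None) -> None:
        self.epoch += 1
        if metric is None:
            raise ValueError("ReduceLROnPlateau requires a metric")
        if metric < self.best - 1e-12:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.bad_epochs = 0


class CyclicLR(Scheduler):
    """Triangular cycle between ``base_lr/div`` and ``base_lr``."""

    def __init__(self, optimizer, step_size: int = 10, div: float = 10.0):
        super().__init__(optimizer)
        self.step_size, self.div = step_size, div

    def _lr_at(self, epoch, metric):
        lo = self.base_lr / self.div
        cycle_pos = (epoch % (2 * self.step_size)) / self.step_size
        frac = cycle_pos if cycle_pos <= 1.0 else 2.0 - cycle_pos
        return lo + (self.base_lr - lo) * frac


OPTIMIZERS = {"sgd": SGD, "adam": Adam, "rmsprop": RMSprop}
SCHEDULERS = {
    "step": StepLR,
    "multistep": MultiStepLR,
    "cosine": CosineAnnealingLR,
    "reduce_on_plateau": ReduceLROnPlateau,
    "cyclic": CyclicLR,
}
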