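"""Optimizers: SGD with momentum, and Adam with either learning-rate decay
(lr / (1 + decay * step), the legacy-Keras reading of "decay") or decoupled
weight decay, selected by ``decay_mode``."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "Adam"]


class SGD:
    def __init__(self, lr: float, momentum: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        self.lr = lr
        self.momentum = momentum
        self._velocity: dict[str, np.ndarray] = {}

    def step(self, network) -> None:
        for name, layer, key in network.parameters(trainable_only=True):
            grad = layer.grads.get(key)
            if grad is None:
                continue
            v = self._velocity.get(name)
            if v is None:
                v = np.zeros_like(layer.params[key])
            v = self.momentum * v - self.lr * grad
            self._velocity[name] = v
            layer.params[key] = layer.params[key] + v


class Adam:
    def __init__(
        self,
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
        decay: float = 0.0,
        decay_mode: str = "lr",
    ):
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        if decay_mode not in ("lr", "weight"):
            raise ValueError("decay_mode must be 'lr' or 'weight'")
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.decay = decay
        self.decay_mode = decay_mode
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, network) -> None:
        self.t += 1
        lr_t = self.lr
        if self.decay_mode == "lr" and self.decay > 0:
            lr_t = self.lr / (1.0 + self.decay * self.t)
        for name, layer, key in network.parameters(trainable_only=True):
            grad = layer.grads.get(key)
            if grad is None:
                continue
            if self.decay_mode == "weight" and self.decay > 0:
                grad = grad + self.decay * layer.params[key]
            m = self._m.get(name, np.zeros_like(layer.params[key]))
            v = self._v.get(name, np.zeros_like(layer.params[key]))
            m = self.beta1 * m + (1 - self.beta1) * grad
            v = self.beta2 * v + (1 - self.beta2) * grad * grad
            self._m[name], self._v[name] = m, v
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            layer.params[key] = layer.params[key] - lr_t * mhat / (
                np.sqrt(vhat) + self.eps
            )
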