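"""Small neural-network building blocks on top of the autodiff core.

Layers use the conventional fan-in uniform initialization
U(-1/sqrt(fan_in), 1/sqrt(fan_in)) for weights and biases, and the
optimizer mirrors Adam with L2 weight decay folded into the gradient,
an epsilon added outside the square root of the (optionally AMSGrad-
maximized) second moment, matching the mainstream deep-learning
convention.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor

__all__ = ["Linear", "MLP", "Adam"]


class Linear:
    """Affine layer y = x @ W + b."""

    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(fan_in)
        self.W = Tensor(rng.uniform(-bound, bound, size=(fan_in, fan_out)),
                        requires_grad=True)
        self.b = Tensor(rng.uniform(-bound, bound, size=(fan_out,)),
                        requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


_ACTIVATIONS = {
    "elu": lambda t: t.elu(),
    "tanh": lambda t: t.tanh(),
    "softplus": lambda t: t.softplus(),
}


class MLP:
    """Two fully connected layers with a smooth rectifier in between."""

    def __init__(self, fan_in: int, hidden: int, fan_out: int,
                 rng: np.random.Generator, activation: str = "elu"):
        self.l1 = Linear(fan_in, hidden, rng)
        self.l2 = Linear(hidden, fan_out, rng)
        self._act = _ACTIVATIONS[activation]

    def __call__(self, x: Tensor) -> Tensor:
        return self.l2(self._act(self.l1(x)))

    def parameters(self):
        return self.l1.parameters() + self.l2.parameters()


class Adam:
    def __init__(self, params, lr=0.01, betas=(0.9, 0.999), eps=0.01,
                 weight_decay=0.01, amsgrad=True):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.amsgrad = amsgrad
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.vmax = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            if self.amsgrad:
                np.maximum(self.vmax[i], vhat, out=self.vmax[i])
                vhat = self.vmax[i]
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
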