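"""Optimizers."""
from __future__ import annotations

import numpy as np


class SGD:
    """SGD with classical momentum and decoupled-from-bias weight decay.

    Weight decay is applied to every parameter except 1-D ones (norm gains,
    biases, scales), mirroring the usual detector training setup.
    """

    def __init__(self, params, lr=0.01, momentum=0.937, weight_decay=0.0005):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
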