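"""AdamW optimizer and a reduce-on-plateau learning-rate scheduler."""

from __future__ import annotations

import numpy as np


class AdamW:
    """Adam with decoupled weight decay (applied to every parameter)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=5e-4):
        self.params = list(params)
        self.lr = float(lr)
        self.betas = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * (g * g)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)


class ReduceLROnPlateau:
    """Halve (by ``factor``) the LR after ``patience`` consecutive epochs
    without improvement of the monitored quantity (minimisation)."""

    def __init__(self, optimizer, factor=0.5, patience=3, min_delta=1e-8):
        self.optimizer = optimizer
        self.factor = float(factor)
        self.patience = int(patience)
        self.min_delta = float(min_delta)
        self.best = np.inf
        self.num_bad = 0

    def step(self, metric):
        metric = float(metric)
        if metric < self.best - self.min_delta:
            self.best = metric
            self.num_bad = 0
        else:
            self.num_bad += 1
            if self.num_bad >= self.patience:
                self.optimizer.lr *= self.factor
                self.num_bad = 0

    @property
    def lr(self):
        return self.optimizer.lr
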