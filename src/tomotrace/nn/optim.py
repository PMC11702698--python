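"""Optimizers and the early-stopping rule shared by both trainable models."""

from __future__ import annotations

import numpy as np

__all__ = ["NAdam", "EarlyStopping"]


class NAdam:
    """Nesterov-momentum Adam (Dozat 2016), matching the common formulation
    with the 0.96^(t*0.004) momentum-decay schedule."""

    def __init__(self, params, lr: float = 2e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, psi: float = 0.004):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.psi = psi
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._mu_prod = 1.0

    def step(self):
        self.t += 1
        t = self.t
        mu_t = self.beta1 * (1.0 - 0.5 * 0.96 ** (t * self.psi))
        mu_next = self.beta1 * (1.0 - 0.5 * 0.96 ** ((t + 1) * self.psi))
        mu_prod_t = self._mu_prod * mu_t
        mu_prod_next = mu_prod_t * mu_next
        self._mu_prod = mu_prod_t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            m_hat = mu_next * m / (1.0 - mu_prod_next) + (1.0 - mu_t) * g / (1.0 - mu_prod_t)
            v_hat = v / (1.0 - self.beta2 ** t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class EarlyStopping:
    """Stop when a moving average of validation loss fails to improve for
    ``patience`` consecutive updates.

    ``window`` is the length of the moving average (1 = raw loss).
    """

    def __init__(self, patience: int, window: int = 1, min_delta: float = 0.0):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        if window < 1:
            raise ValueError("window must be >= 1")
        self.patience = patience
        self.window = window
        self.min_delta = min_delta
        self.best = np.inf
        self.stale = 0
        self._history: list[float] = []

    def update(self, loss: float) -> bool:
        """Record one validation loss; return True when training should stop."""
        self._history.append(float(loss))
        ma = float(np.mean(self._history[-self.window:]))
        if ma < self.best - self.min_delta:
            self.best = ma
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience
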