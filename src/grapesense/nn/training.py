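"""Optimizer and loss for the spectral networks."""

from __future__ import annotations

import numpy as np

from .layers import DTYPE, Sequential


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int) -> None:
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


def softmax_cross_entropy(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the scores.

    Scores are pre-softmax logits (n, n_classes); labels are integer classes.
    """
    z = scores - scores.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = scores.shape[0]
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + 1e-12)))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(scores.dtype)


class Adam:
    """Adaptive moment estimation over a network's parameter tensors."""

    def __init__(self, net: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._state: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, name in self.net.parameters():
            grad = layer.grads.get(name)
            if grad is None:
                continue
            key = (id(layer), name)
            if key not in self._state:
                self._state[key] = (np.zeros_like(layer.params[name]),
                                    np.zeros_like(layer.params[name]))
            m, v = self._state[key]
            m = b1 * m + (1 - b1) * grad
            v = b2 * v + (1 - b2) * grad * grad
            self._state[key] = (m, v)
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            layer.params[name] -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(
                layer.params[name].dtype
            )
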