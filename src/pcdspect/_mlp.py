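"""Minimal fully-connected network trainer (numpy).

Supports the decomposition MLP: ReLU hidden layers, linear output, Adam with
L2 weight decay, inverted dropout on hidden activations, and a smooth-L1
(Huber-like) loss.  Training is full-batch and deterministic for a given
seed.  Problem sizes here are tiny (tens of calibration samples, a few
hundred weights per layer), so plain numpy is entirely adequate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def parameter_count(n_inputs: int, hidden: tuple[int, ...], n_outputs: int) -> int:
    """Trainable parameters (weights + biases) of the fully-connected net."""
    sizes = (n_inputs, *hidden, n_outputs)
    return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))


def _smooth_l1(residual: np.ndarray, beta: float) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise smooth-L1 loss and its derivative w.r.t. the residual."""
    a = np.abs(residual)
    quad = a < beta
    loss = np.where(quad, 0.5 * residual ** 2 / beta, a - 0.5 * beta)
    grad = np.where(quad, residual / beta, np.sign(residual))
    return loss, grad


@dataclass
class MLPNetwork:
    """Weights of a trained network; predict() is deterministic (no dropout)."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @property
    def hidden_sizes(self) -> tuple[int, ...]:
        return tuple(w.shape[1] for w in self.weights[:-1])

    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def predict(self, x: np.ndarray) -> np.ndarray:
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ w + b, 0.0)
        return h @ self.weights[-1] + self.biases[-1]


def train_mlp(x: np.ndarray, y: np.ndarray, hidden: tuple[int, ...],
              *, lr: float = 1e-3, epochs: int = 2000, dropout: float = 0.01,
              weight_decay: float = 1e-4, smooth_l1_beta: float = 1.0,
              lr_schedule: str = "cosine", seed: int = 0) -> MLPNetwork:
    """Full-batch Adam training; raises on non-finite loss.

    With the default cosine schedule the learning rate anneals from ``lr``
    to zero over the run, which averages out the dropout-induced gradient
    noise in the final phase; ``lr_schedule="constant"`` disables this.
    """
    rng = np.random.default_rng(seed)
    sizes = (x.shape[1], *hidden, y.shape[1])
    ws = [rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b))
          for a, b in zip(sizes[:-1], sizes[1:])]
    bs = [np.zeros(b) for b in sizes[1:]]

    mw = [np.zeros_like(w) for w in ws]
    vw = [np.zeros_like(w) for w in ws]
    mb = [np.zeros_like(b) for b in bs]
    vb = [np.zeros_like(b) for b in bs]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    n = x.shape[0]

    if lr_schedule not in ("cosine", "constant"):
        raise ValueError("lr_schedule must be 'cosine' or 'constant'")

    for t in range(1, epochs + 1):
        if lr_schedule == "cosine":
            lr_t = lr * 0.5 * (1.0 + np.cos(np.pi * (t - 1) / epochs))
        else:
            lr_t = lr
        # forward with inverted dropout on hidden activations
        acts = [x]
        masks = []
        h = x
        for w, b in zip(ws[:-1], bs[:-1]):
            h = np.maximum(h @ w + b, 0.0)
            if dropout > 0:
                keep = rng.random(h.shape) >= dropout
                h = h * keep / (1.0 - dropout)
                masks.append(keep)
            else:
                masks.append(None)
            acts.append(h)
        out = h @ ws[-1] + bs[-1]
        loss_el, dres = _smooth_l1(out - y, smooth_l1_beta)
        if not np.isfinite(loss_el.sum()):
            raise FloatingPointError("non-finite training loss")

        # backward
        grad = dres / (n * y.shape[1])
        gws = [None] * len(ws)
        gbs = [None] * len(bs)
        for li in range(len(ws) - 1, -1, -1):
            gws[li] = acts[li].T @ grad + weight_decay * ws[li]
            gbs[li] = grad.sum(axis=0)
            if li > 0:
                grad = grad @ ws[li].T
                if masks[li - 1] is not None:
                    grad = grad * masks[li - 1] / (1.0 - dropout)
                grad = grad * (acts[li] > 0)

        # Adam update
        c1, c2 = 1 - beta1 ** t, 1 - beta2 ** t
        for li in range(len(ws)):
            mw[li] = beta1 * mw[li] + (1 - beta1) * gws[li]
            vw[li] = beta2 * vw[li] + (1 - beta2) * gws[li] ** 2
            ws[li] -= lr_t * (mw[li] / c1) / (np.sqrt(vw[li] / c2) + eps)
            mb[li] = beta1 * mb[li] + (1 - beta1) * gbs[li]
            vb[li] = beta2 * vb[li] + (1 - beta2) * gbs[li] ** 2
            bs[li] -= lr_t * (mb[li] / c1) / (np.sqrt(vb[li] / c2) + eps)

    return MLPNetwork(weights=ws, biases=bs)
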