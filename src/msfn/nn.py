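"""Minimal dense/convolution primitives with explicit gradients.

The two neural branches (graph-convolutional and per-view convolutional)
are small full-batch models, so a compact numpy implementation with
hand-written backward passes and an Adam optimizer is sufficient and keeps
training bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(
    logits: np.ndarray, y: np.ndarray, weight: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits.

    ``weight`` is a per-sample weight (e.g. a 0/1 training mask); the loss
    is averaged over the total weight.
    """
    n = len(logits)
    p = softmax(logits)
    if weight is None:
        weight = np.ones(n)
    total = weight.sum()
    eps = 1e-12
    loss = float(-(weight * np.log(p[np.arange(n), y] + eps)).sum() / total)
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (weight / total)[:, None]
    return loss, grad


def dropout_mask(rng: np.random.Generator, shape: tuple[int, ...], p: float) -> np.ndarray:
    """Inverted-dropout multiplier: zeros with probability p, else 1/(1-p)."""
    if p <= 0:
        return np.ones(shape)
    return (rng.random(shape) >= p) / (1.0 - p)


def conv1d_same(x: np.ndarray, kernel: np.ndarray, bias: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1-D convolution with same-padding.

    x: (n, f) single-channel sequences; kernel: (k, c); bias: (c,).
    Returns the (n, f, c) feature maps and the (n, f, k) patch tensor
    (cached for the backward pass).
    """
    k = kernel.shape[0]
    left, right = (k - 1) // 2, k // 2
    padded = np.pad(x, ((0, 0), (left, right)))
    patches = sliding_window_view(padded, k, axis=1)  # (n, f, k)
    return patches @ kernel + bias, patches


def conv1d_same_backward(
    d_out: np.ndarray, patches: np.ndarray, kernel: np.ndarray, n_cols: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of conv1d_same w.r.t. input, kernel and bias."""
    k = kernel.shape[0]
    left = (k - 1) // 2
    d_kernel = np.einsum("nfk,nfc->kc", patches, d_out)
    d_bias = d_out.sum(axis=(0, 1))
    d_patches = d_out @ kernel.T  # (n, f, k)
    n, f = d_patches.shape[:2]
    d_padded = np.zeros((n, n_cols + k - 1))
    for offset in range(k):
        d_padded[:, offset : offset + f] += d_patches[:, :, offset]
    d_x = d_padded[:, left : left + n_cols]
    return d_x, d_kernel, d_bias


class Adam:
    """Adam over a dict of named parameter arrays, updated in place."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            m_hat = self.m[key] / (1 - b1**self.t)
            v_hat = self.v[key] / (1 - b2**self.t)
            self.params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
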