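"""Minimal dense-network core shared by the GIN encoder and the PLANS MLPs.

Fully connected layers with manual backpropagation, ReLU hidden
activations, inverted dropout, softmax / sigmoid output losses, and Adam.
All arithmetic is float32 NumPy; every source of randomness takes an
explicit ``numpy.random.Generator`` so runs are reproducible bit-for-bit
on the same platform.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Dense:
    """Affine layer ``y = x W + b`` with He-scaled initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        # Gradients accumulate; Adam.step() zeroes them after the update.
        self.dW += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.W.T

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]


class MLPNet:
    """Stack of Dense layers, ReLU between them, linear final layer.

    ``dropout_rate`` > 0 applies inverted dropout to the activation
    feeding the final layer, and only when ``forward(..., train=True)``
    is given an rng — the convention used for noisy-student training,
    where teachers run inference with all noise off.
    """

    def __init__(self, dims, rng: np.random.Generator, dropout_rate: float = 0.0):
        if len(dims) < 2:
            raise ValueError("need at least input and output dims")
        self.dims = list(dims)
        self.dropout_rate = float(dropout_rate)
        self.layers = [Dense(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self._relu_masks: list[np.ndarray] = []
        self._drop_mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        self._relu_masks = []
        self._drop_mask = None
        for i, layer in enumerate(self.layers):
            last = i == len(self.layers) - 1
            if last and train and self.dropout_rate > 0.0 and rng is not None:
                keep = 1.0 - self.dropout_rate
                mask = (rng.random(x.shape) < keep).astype(DTYPE) / DTYPE(keep)
                x = x * mask
                self._drop_mask = mask
            x = layer.forward(x)
            if not last:
                mask = x > 0
                x = x * mask
                self._relu_masks.append(mask)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for i in range(len(self.layers) - 1, -1, -1):
            if i < len(self.layers) - 1:
                dout = dout * self._relu_masks[i]
            dout = self.layers[i].backward(dout)
            if i == len(self.layers) - 1 and self._drop_mask is not None:
                dout = dout * self._drop_mask
        return dout

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.parameters()))


class Adam:
    """Adam over a list of ``(param, grad)`` array pairs, updated in place."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            g[...] = 0.0

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy -sum_i y_i log p_i with soft targets.

    Returns ``(loss, dlogits)`` where dlogits is the gradient of the mean
    loss with respect to the logits.
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = -float(np.sum(targets * np.log(p + 1e-12)) / n)
    dlogits = (p - targets).astype(DTYPE) / DTYPE(n)
    return loss, dlogits


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid_bce(logits: np.ndarray, targets: np.ndarray):
    """Mean per-bit binary cross-entropy after sigmoid; returns (loss, dlogits)."""
    p = sigmoid(logits.astype(np.float64))
    t = targets.astype(np.float64)
    loss = float(-np.mean(t * np.log(p + 1e-12) + (1.0 - t) * np.log(1.0 - p + 1e-12)))
    dlogits = ((p - t) / p.size).astype(DTYPE)
    return loss, dlogits


def snapshot(params) -> list[np.ndarray]:
    return [p.copy() for p, _ in params]


def restore(params, saved) -> None:
    for (p, _), s in zip(params, saved):
        p[...] = s
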