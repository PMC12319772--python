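"""Minimal feed-forward network with hand-derived gradients.

A small, self-contained MLP (dense layers, ReLU, inverted dropout, softmax
head) plus an Adam optimizer.  Backpropagation is written out explicitly:
``forward`` caches activations and ``backward`` consumes the gradient of the
loss with respect to the pre-softmax logits, so any differentiable loss —
cross-entropy or the Real-Logic satisfaction loss — can drive the same
network.  Gradient correctness is pinned by a finite-difference test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["NetworkSpec", "MLP", "Adam", "softmax"]

_ACTIVATIONS = ("relu", "tanh", "sigmoid")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description: layer widths (input ... output), activation, dropout.

    The final width is the number of classes (2 for active/inactive); dropout
    is the drop probability applied to hidden activations during training.
    """

    layer_widths: tuple[int, ...] = (None, 384, 192, 2)  # input width filled at build time
    activation: str = "relu"
    dropout: float = 0.25

    def __post_init__(self) -> None:
        if len(self.layer_widths) < 2:
            raise ValueError("need at least an input and an output layer")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")

    def with_input_dim(self, dim: int) -> "NetworkSpec":
        return NetworkSpec((int(dim),) + tuple(self.layer_widths[1:]), self.activation, self.dropout)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MLP:
    """Dense feed-forward classifier with a softmax output head."""

    def __init__(self, spec: NetworkSpec, seed: int = 42) -> None:
        if spec.layer_widths[0] is None:
            raise ValueError("input width unset; use NetworkSpec.with_input_dim")
        self.spec = spec
        self.layer_widths = tuple(int(w) for w in spec.layer_widths)
        self.rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.layer_widths[:-1], self.layer_widths[1:]):
            # He initialisation, appropriate for ReLU-family hidden layers
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(self.rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._cache: dict | None = None

    # -- forward / backward -------------------------------------------------

    def _act(self, z: np.ndarray) -> np.ndarray:
        if self.spec.activation == "relu":
            return np.maximum(z, 0.0)
        if self.spec.activation == "tanh":
            return np.tanh(z)
        return 1.0 / (1.0 + np.exp(-z))

    def _act_grad(self, z: np.ndarray) -> np.ndarray:
        # computed from pre-activations: cached activations are post-dropout
        if self.spec.activation == "relu":
            return (z > 0.0).astype(z.dtype)
        if self.spec.activation == "tanh":
            return 1.0 - np.tanh(z) ** 2
        s = 1.0 / (1.0 + np.exp(-z))
        return s * (1.0 - s)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Softmax class probabilities; caches intermediates when training."""
        a = np.asarray(x, dtype=np.float64)
        pre, acts, masks = [], [a], []
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            if i < len(self.weights) - 1:
                a = self._act(z)
                if training and self.spec.dropout > 0.0:
                    keep = 1.0 - self.spec.dropout
                    mask = (self.rng.random(a.shape) < keep) / keep
                    a = a * mask
                else:
                    mask = None
                masks.append(mask)
            else:
                a = softmax(z)
            pre.append(z)
            acts.append(a)
        self._cache = {"pre": pre, "acts": acts, "masks": masks} if training else None
        if training:
            self._cache["x"] = np.asarray(x, dtype=np.float64)
        return a

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Deterministic (dropout-free) class probabilities."""
        return self.forward(x, training=False)

    def backward(self, dlogits: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Backpropagate dL/dlogits from the last training forward pass."""
        if self._cache is None:
            raise RuntimeError("backward requires a preceding forward(training=True)")
        pre, acts, masks = self._cache["pre"], self._cache["acts"], self._cache["masks"]
        grads_w = [np.empty_like(w) for w in self.weights]
        grads_b = [np.empty_like(b) for b in self.biases]
        delta = np.asarray(dlogits, dtype=np.float64)
        for i in range(len(self.weights) - 1, -1, -1):
            a_prev = acts[i]
            grads_w[i] = a_prev.T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                delta = delta * self._act_grad(pre[i - 1])
        return grads_w, grads_b

    # -- parameter plumbing (used by optimizers and finite-difference tests) -

    @property
    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def get_flat(self) -> np.ndarray:
        return np.concatenate([p.ravel() for p in self.parameters])

    def set_flat(self, flat: np.ndarray) -> None:
        offset = 0
        for p in self.parameters:
            p[...] = flat[offset : offset + p.size].reshape(p.shape)
            offset += p.size

    def clone(self) -> "MLP":
        other = MLP(self.spec, seed=0)
        for dst, src in zip(other.parameters, self.parameters):
            dst[...] = src
        return other


class Adam:
    """Adam with the standard defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: Sequence[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * g
            v[...] = self.beta2 * v + (1.0 - self.beta2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
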