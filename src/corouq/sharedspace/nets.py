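"""Small dense networks built on the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class MLP:
    """Fully connected network with tanh hidden activations, linear output."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.sizes = list(sizes)
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / (n_in + n_out))  # Glorot
            self.weights.append(Tensor(rng.normal(0.0, scale, size=(n_in, n_out)),
                                       requires_grad=True))
            self.biases.append(Tensor(np.zeros(n_out), requires_grad=True))

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        n_layers = len(self.weights)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < n_layers - 1:
                h = h.tanh()
        return h

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        """Pure-numpy forward pass for inference."""
        h = np.asarray(x, float)
        n_layers = len(self.weights)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W.value + b.value
            if i < n_layers - 1:
                h = np.tanh(h)
        return h

    def parameters(self) -> list[Tensor]:
        return [*self.weights, *self.biases]

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.parameters(), state):
            p.value = v.copy()


class Standardizer:
    """Z-score transform fitted on pilot statistics."""

    def __init__(self, data: np.ndarray):
        data = np.atleast_2d(np.asarray(data, float))
        self.mean = data.mean(axis=0)
        self.std = np.maximum(data.std(axis=0), 1e-12)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.mean) / self.std

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, float) * self.std + self.mean
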