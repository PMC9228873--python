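"""Minimal dense-network engine: layers, activations, dropout, Adam.

Networks here are tiny (at most three hidden layers, widths 4-512), so plain
numpy forward/backward passes are entirely adequate.  All stochastic pieces
(initialisation, dropout masks) draw from generators passed in by the caller.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


#: activation -> (f, f' as a function of the activation output a)
ACTIVATIONS = {
    "sigmoid": (_sigmoid, lambda a: a * (1.0 - a)),
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
    "relu": (lambda z: np.maximum(z, 0.0), lambda a: (a > 0.0).astype(a.dtype)),
    "linear": (lambda z: z, lambda a: np.ones_like(a)),
}


class Dense:
    """Affine layer with Glorot-uniform initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.W.T

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.gW, self.gb]


class MLP:
    """Multi-layer perceptron with one activation on hidden layers.

    The output layer is always linear; squashing (e.g. a sigmoid for a
    discriminator probability) is applied by the caller so that losses can be
    back-propagated through numerically stable logit expressions.
    Dropout (inverted scaling) acts on hidden activations during training.
    """

    def __init__(
        self,
        sizes: list[int],
        hidden_activation: str,
        dropout: float,
        rng: np.random.Generator,
    ):
        if hidden_activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {hidden_activation!r}")
        if not 0.0 <= dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {dropout}")
        self.activation = hidden_activation
        self.dropout = dropout
        self.layers = [Dense(sizes[i], sizes[i + 1], rng) for i in range(len(sizes) - 1)]
        self._acts: list[np.ndarray] = []
        self._masks: list[np.ndarray | None] = []

    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        act, _ = ACTIVATIONS[self.activation]
        self._acts, self._masks = [], []
        h = x
        for layer in self.layers[:-1]:
            h = act(layer.forward(h))
            self._acts.append(h)
            if train and self.dropout > 0.0:
                mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * mask
                self._masks.append(mask)
            else:
                self._masks.append(None)
        return self.layers[-1].forward(h)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        """Back-propagate dL/d(output); fills layer grads, returns dL/d(input)."""
        _, dact = ACTIVATIONS[self.activation]
        grad = self.layers[-1].backward(grad_out)
        for i in range(len(self.layers) - 2, -1, -1):
            if self._masks[i] is not None:
                grad = grad * self._masks[i]
            grad = grad * dact(self._acts[i])
            grad = self.layers[i].backward(grad)
        return grad

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s


class Adam:
    """Adam optimiser over a fixed list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * g
            v[...] = self.beta2 * v + (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
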