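"""Sequential container, sigmoid/BCE loss and the Adam optimizer."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class TrainingError(RuntimeError):
    """Raised when the loss diverges (NaN/inf), reporting epoch and batch."""


class Sequential:
    """An ordered stack of layers producing multi-label logits."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None,
                col0: np.ndarray | None = None) -> np.ndarray:
        """Run the stack; ``col0`` optionally feeds a pre-unfolded input to
        the first (convolutional) layer, bypassing its im2col."""
        for i, layer in enumerate(self.layers):
            if i == 0 and col0 is not None:
                x = layer.forward(x, train=train, rng=rng, col=col0)
            else:
                x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def forward_to(self, x: np.ndarray, layer_index: int) -> np.ndarray:
        """Eval-mode activations after ``layers[layer_index]`` (inclusive)."""
        for layer in self.layers[:layer_index + 1]:
            x = layer.forward(x, train=False)
        return x

    # -------------------------------------------------------------- weights
    def parameters(self):
        """Yield (layer, name, array, decayed) for every trainable tensor."""
        for layer in self.layers:
            for name, arr in layer.params.items():
                yield layer, name, arr, name in layer.decayed

    def n_parameters(self) -> int:
        return sum(arr.size for _, _, arr, _ in self.parameters())

    def state(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(v.copy() for v in layer.params.values())
            for extra in ("running_mean", "running_var"):
                if hasattr(layer, extra):
                    out.append(getattr(layer, extra).copy())
        return out

    def load_state(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for layer in self.layers:
            for name in layer.params:
                layer.params[name][...] = next(it)
            for extra in ("running_mean", "running_var"):
                if hasattr(layer, extra):
                    getattr(layer, extra)[...] = next(it)

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Sigmoid class probabilities in eval mode, computed in chunks."""
        out = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i:i + batch_size], train=False)
            out.append(sigmoid(logits))
        return np.concatenate(out, axis=0)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Multi-task binary cross-entropy: summed over classes, averaged over batch.

    This is the standard reduction for multi-label genomics networks (each
    class contributes its full per-task loss).  Returns the loss and its
    gradient w.r.t. the logits; the two are fused for numerical stability
    (log-sum-exp form, gradient ``sigmoid(z) - y``).
    """
    z = logits.astype(np.float64, copy=False)
    y = targets.astype(np.float64, copy=False)
    per_entry = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    loss = per_entry.sum(axis=1).mean()
    grad = ((sigmoid(logits) - targets.astype(logits.dtype)) / logits.shape[0]
            ).astype(logits.dtype)
    return float(loss), grad


class Adam:
    """Adam with default moment decays and decoupled-from-biases L2.

    The L2 penalty (strength ``l2``, applied as ``l2 * sum(W**2)``, so the
    gradient contribution is ``2 * l2 * W``) touches only weight matrices,
    never biases or batch-norm scale/shift.
    """

    def __init__(self, model: Sequential, lr: float = 3e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, l2: float = 1e-6) -> None:
        self.model = model
        self.lr, self.b1, self.b2, self.eps, self.l2 = lr, beta1, beta2, eps, l2
        self.t = 0
        self.m = [np.zeros_like(a) for _, _, a, _ in model.parameters()]
        self.v = [np.zeros_like(a) for _, _, a, _ in model.parameters()]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (layer, name, arr, decayed) in enumerate(self.model.parameters()):
            g = layer.grads[name]
            if decayed and self.l2:
                g = g + (2.0 * self.l2) * arr
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            arr -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
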