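"""Minimal feedforward classifier: dense ReLU stack, dropout, rmsprop.

A deliberately small, dependency-free implementation of the staging
network: input -> 300 -> 100 -> n_classes, ReLU hidden activations,
inverted dropout (rate 0.2) after each hidden layer during training,
softmax output trained with categorical cross-entropy under the rmsprop
update rule. Fully deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DenseNet"]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DenseNet:
    """Fully connected softmax classifier trained with rmsprop.

    Parameters
    ----------
    layer_sizes : e.g. (144, 300, 100, 5) — input, hidden..., output.
    dropout_rate : drop probability after each hidden layer (training only).
    lr, rho, eps : rmsprop step size, decay and stabilizer.
    seed : controls weight init, dropout masks and batch shuffling.
    """

    def __init__(
        self,
        layer_sizes: tuple,
        dropout_rate: float = 0.2,
        lr: float = 1e-3,
        rho: float = 0.9,
        eps: float = 1e-7,
        seed: int = 0,
    ) -> None:
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        self.layer_sizes = tuple(int(s) for s in layer_sizes)
        self.dropout_rate = float(dropout_rate)
        self.lr, self.rho, self.eps = lr, rho, eps
        self.rng = np.random.default_rng(seed)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            # He initialization for the ReLU stack
            self.W.append(self.rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in))
            self.b.append(np.zeros(fan_out))
        self._cache_W = [np.zeros_like(w) for w in self.W]
        self._cache_b = [np.zeros_like(b) for b in self.b]

    @property
    def n_params(self) -> int:
        return int(sum(w.size + b.size for w, b in zip(self.W, self.b)))

    # ------------------------------------------------------------------
    def _forward(self, X: np.ndarray, train: bool) -> tuple[np.ndarray, list]:
        acts = [X]
        h = X
        n_hidden = len(self.W) - 1
        masks = []
        for i in range(n_hidden):
            h = np.maximum(h @ self.W[i] + self.b[i], 0.0)
            if train and self.dropout_rate > 0:
                mask = (self.rng.random(h.shape) >= self.dropout_rate) / (1 - self.dropout_rate)
                h = h * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(h)
        probs = _softmax(h @ self.W[-1] + self.b[-1])
        return probs, [acts, masks]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs, _ = self._forward(np.asarray(X, dtype=float), train=False)
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # ------------------------------------------------------------------
    def _rmsprop_step(self, grads_W: list, grads_b: list) -> None:
        for i, (gw, gb) in enumerate(zip(grads_W, grads_b)):
            self._cache_W[i] = self.rho * self._cache_W[i] + (1 - self.rho) * gw**2
            self._cache_b[i] = self.rho * self._cache_b[i] + (1 - self.rho) * gb**2
            self.W[i] -= self.lr * gw / (np.sqrt(self._cache_W[i]) + self.eps)
            self.b[i] -= self.lr * gb / (np.sqrt(self._cache_b[i]) + self.eps)

    def _batch_update(self, Xb: np.ndarray, yb: np.ndarray) -> float:
        m = Xb.shape[0]
        probs, (acts, masks) = self._forward(Xb, train=True)
        eps = 1e-12
        loss = -float(np.mean(np.log(probs[np.arange(m), yb] + eps)))
        delta = probs.copy()
        delta[np.arange(m), yb] -= 1.0
        delta /= m
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        grads_W[-1] = acts[-1].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        for i in range(len(self.W) - 2, -1, -1):
            delta = delta @ self.W[i + 1].T
            if masks[i] is not None:
                delta = delta * masks[i]
            delta = delta * (acts[i + 1] > 0)
            grads_W[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
        self._rmsprop_step(grads_W, grads_b)
        return loss

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 100,
        batch_size: int = 64,
    ) -> list[float]:
        """Train; returns the per-epoch mean training loss."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n = X.shape[0]
        losses = []
        for _ in range(epochs):
            idx = self.rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, batch_size):
                sel = idx[start : start + batch_size]
                epoch_loss += self._batch_update(X[sel], y[sel])
                n_batches += 1
            losses.append(epoch_loss / n_batches)
        return losses
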