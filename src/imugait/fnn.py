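"""A small fully-connected regression network with dropout and max-norm.

Architecture used for vGRF regression: an input layer matching the
feature count, five hidden layers of ten rectified-linear units, and a
single linear output. Training minimizes the batch RMSE with the Adam
optimizer; inverted dropout follows every hidden activation, and after
each update the incoming-weight vector of every hidden unit is rescaled
so its Euclidean norm never exceeds ``max_weight_norm`` (the classic
companion constraint to dropout). Early stopping monitors a validation
split and restores the best weights.

Everything is plain numpy, seeded through one generator, so training is
bit-reproducible for a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FNNConfig", "FeedForwardNet"]


@dataclass
class FNNConfig:
    """Hyperparameters of the feedforward vGRF regressor."""

    hidden_layers: int = 5
    neurons_per_layer: int = 10
    dropout_rate: float = 0.05
    max_weight_norm: float = 4.0
    epochs: int = 400
    batch_size: int = 128
    learning_rate: float = 3e-3
    lr_decay: float = 0.5
    lr_decay_every: int = 100
    patience: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_layers < 1 or self.neurons_per_layer < 1:
            raise ValueError("layer sizes must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        if self.max_weight_norm <= 0:
            raise ValueError("max weight norm must be positive")


class FeedForwardNet:
    """5x10 ReLU regressor trained with Adam on an RMSE loss."""

    def __init__(self, n_features: int, config: FNNConfig | None = None):
        self.config = config or FNNConfig()
        self.n_features = int(n_features)
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        sizes = [self.n_features] + [cfg.neurons_per_layer] * cfg.hidden_layers + [1]
        self.weights = [
            rng.normal(scale=np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._rng = rng
        self.history_: dict[str, list[float]] = {"train_rmse": [], "val_rmse": []}

    # -- forward ---------------------------------------------------------

    def _forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        """Forward pass; with ``rng``, applies inverted dropout and caches."""
        cfg = self.config
        acts = [x]
        masks = []
        h = x
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            if i < n_layers - 1:
                h = np.maximum(z, 0.0)
                if rng is not None and cfg.dropout_rate > 0:
                    mask = (
                        rng.random(h.shape) >= cfg.dropout_rate
                    ) / (1.0 - cfg.dropout_rate)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                h = z
            acts.append(h)
        return acts, masks

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Deterministic predictions (dropout disabled), shape (n,)."""
        x = np.asarray(x, dtype=float)
        acts, _ = self._forward(x)
        return acts[-1][:, 0]

    # -- training --------------------------------------------------------

    def _backward(self, acts, masks, y: np.ndarray):
        """Gradients of the batch RMSE w.r.t. weights and biases."""
        yhat = acts[-1][:, 0]
        resid = yhat - y
        m = len(y)
        batch_rmse = float(np.sqrt(np.mean(resid**2)))
        if batch_rmse < 1e-12:
            zero_w = [np.zeros_like(w) for w in self.weights]
            zero_b = [np.zeros_like(b) for b in self.biases]
            return zero_w, zero_b, batch_rmse
        # d(rmse)/d(yhat) = resid / (m * rmse)
        delta = (resid / (m * batch_rmse))[:, None]
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        for i in range(len(self.weights) - 1, -1, -1):
            grads_w[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                delta = delta * (acts[i] > 0)
        return grads_w, grads_b, batch_rmse

    def _clip_max_norm(self) -> None:
        cap = self.config.max_weight_norm
        for i in range(len(self.weights) - 1):  # hidden layers only
            norms = np.linalg.norm(self.weights[i], axis=0, keepdims=True)
            scale = np.minimum(1.0, cap / np.maximum(norms, 1e-12))
            self.weights[i] *= scale

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        verbose: bool = False,
    ) -> "FeedForwardNet":
        """Train with Adam; early-stop on validation RMSE if a split is given."""
        cfg = self.config
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("training data contains NaN or inf")
        if x.shape[0] == 0:
            raise ValueError("empty training data")
        rng = self._rng
        m_w = [np.zeros_like(w) for w in self.weights]
        v_w = [np.zeros_like(w) for w in self.weights]
        m_b = [np.zeros_like(b) for b in self.biases]
        v_b = [np.zeros_like(b) for b in self.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_state = None
        stall = 0
        for epoch in range(cfg.epochs):
            lr = cfg.learning_rate * cfg.lr_decay ** (epoch // cfg.lr_decay_every)
            order = rng.permutation(x.shape[0])
            epoch_losses = []
            for start in range(0, x.shape[0], cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                acts, masks = self._forward(x[idx], rng=rng)
                grads_w, grads_b, loss = self._backward(acts, masks, y[idx])
                epoch_losses.append(loss)
                step += 1
                for i in range(len(self.weights)):
                    m_w[i] = beta1 * m_w[i] + (1 - beta1) * grads_w[i]
                    v_w[i] = beta2 * v_w[i] + (1 - beta2) * grads_w[i] ** 2
                    m_b[i] = beta1 * m_b[i] + (1 - beta1) * grads_b[i]
                    v_b[i] = beta2 * v_b[i] + (1 - beta2) * grads_b[i] ** 2
                    mhat_w = m_w[i] / (1 - beta1**step)
                    vhat_w = v_w[i] / (1 - beta2**step)
                    mhat_b = m_b[i] / (1 - beta1**step)
                    vhat_b = v_b[i] / (1 - beta2**step)
                    self.weights[i] -= lr * mhat_w / (np.sqrt(vhat_w) + eps)
                    self.biases[i] -= lr * mhat_b / (np.sqrt(vhat_b) + eps)
                self._clip_max_norm()
            self.history_["train_rmse"].append(float(np.mean(epoch_losses)))
            if x_val is not None and y_val is not None:
                val_rmse = float(
                    np.sqrt(np.mean((self.predict(x_val) - np.asarray(y_val)) ** 2))
                )
                self.history_["val_rmse"].append(val_rmse)
                if val_rmse < best_val - 1e-6:
                    best_val = val_rmse
                    best_state = (
                        [w.copy() for w in self.weights],
                        [b.copy() for b in self.biases],
                    )
                    stall = 0
                else:
                    stall += 1
                    if stall >= cfg.patience:
                        break
            if verbose:
                print(f"epoch {epoch}: train {self.history_['train_rmse'][-1]:.4f}")
        if best_state is not None:
            self.weights, self.biases = best_state
        return self

    # -- persistence -----------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "config": vars(self.config),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "FeedForwardNet":
        net = cls(state["n_features"], FNNConfig(**state["config"]))
        net.weights = [np.array(w) for w in state["weights"]]
        net.biases = [np.array(b) for b in state["biases"]]
        return net
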