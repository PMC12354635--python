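"""Sequential network container, Adam optimiser, plateau LR schedule."""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .layers import Layer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = -np.sum(onehot * np.log(np.clip(probs, 1e-12, None))) / n
    return float(loss), (probs - onehot) / n


class Network:
    """An ordered stack of layers with shared forward/backward plumbing."""

    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for layer in self.layers:
            out.update(layer.params())
        return out

    def trainable_params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for layer in self.layers:
            if layer.trainable:
                out.update(layer.params())
        return out

    def trainable_grads(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for layer in self.layers:
            if layer.trainable:
                out.update(layer.grads())
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        chunks = [
            softmax(self.forward(x[i : i + batch_size], train=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"parameter name mismatch: {sorted(missing)}")
        for name, value in state.items():
            if params[name].shape != value.shape:
                raise ValueError(f"shape mismatch for {name}")
            params[name][...] = value


class Adam:
    """Adam with per-tensor state; only trainable layers are updated."""

    def __init__(
        self,
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ) -> None:
        self.learning_rate = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, network: Network) -> None:
        self.t += 1
        params = network.trainable_params()
        grads = network.trainable_grads()
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for name, p in params.items():
            g = grads[name]
            m = self._m.setdefault(name, np.zeros_like(p))
            v = self._v.setdefault(name, np.zeros_like(p))
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.learning_rate * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclasses.dataclass
class PlateauSchedule:
    """Halve the learning rate when validation loss stalls.

    If the monitored loss has not improved for ``patience`` consecutive
    epochs, the rate is multiplied by ``factor`` (never below ``min_lr``).
    Once the rate sits at ``min_lr`` and a further full patience window
    passes without improvement, :meth:`update` reports that training should
    stop.  This couples the rate schedule to a guaranteed-terminating
    stopping rule.
    """

    factor: float = 0.5
    patience: int = 5
    min_lr: float = 1e-6

    best: float = np.inf
    wait: int = 0

    def update(self, optimizer: Adam, val_loss: float) -> bool:
        """Record one epoch's validation loss; return True to stop training."""
        if val_loss < self.best - 1e-12:
            self.best = val_loss
            self.wait = 0
            return False
        self.wait += 1
        if self.wait >= self.patience:
            at_floor = optimizer.learning_rate <= self.min_lr * (1 + 1e-9)
            if at_floor:
                return True
            optimizer.learning_rate = max(optimizer.learning_rate * self.factor, self.min_lr)
            self.wait = 0
        return False


@dataclasses.dataclass
class TrainSettings:
    """One training phase's optimisation settings."""

    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 100
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    min_learning_rate: float = 1e-6


def fit(
    network: Network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    settings: TrainSettings,
    rng: np.random.Generator,
    augment_fn=None,
) -> list[dict[str, float]]:
    """Mini-batch training loop with the plateau schedule.

    ``augment_fn(batch_images, rng) -> batch_images`` is applied to each
    training batch if given.  Labels are integer class indices.  Returns the
    per-epoch history (losses, accuracies, learning rate).
    """
    n_classes = int(max(y_train.max(), y_val.max())) + 1
    optimizer = Adam(learning_rate=settings.learning_rate)
    schedule = PlateauSchedule(
        factor=settings.plateau_factor,
        patience=settings.plateau_patience,
        min_lr=settings.min_learning_rate,
    )
    history: list[dict[str, float]] = []
    n = len(x_train)
    for epoch in range(settings.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n, settings.batch_size):
            idx = order[start : start + settings.batch_size]
            xb = x_train[idx]
            if augment_fn is not None:
                xb = augment_fn(xb, rng)
            yb = np.eye(n_classes)[y_train[idx]]
            logits = network.forward(xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            network.backward(dlogits)
            optimizer.step(network)
            epoch_loss += loss * len(idx)
            epoch_correct += int((logits.argmax(axis=1) == y_train[idx]).sum())
        val_probs = network.predict_proba(x_val)
        val_loss = float(
            -np.mean(np.log(np.clip(val_probs[np.arange(len(y_val)), y_val], 1e-12, None)))
        )
        val_acc = float((val_probs.argmax(axis=1) == y_val).mean())
        history.append(
            {
                "epoch": epoch + 1,
                "learning_rate": optimizer.learning_rate,
                "train_loss": epoch_loss / n,
                "train_accuracy": epoch_correct / n,
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        if schedule.update(optimizer, val_loss):
            break
    return history
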