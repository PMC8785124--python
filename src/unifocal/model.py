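"""A tiny convolutional encoder–decoder segmenter trained with plain SGD.

This is a desk-scale stand-in for a full U-Net: three same-padding 3x3
convolution layers (1 → hidden → hidden → C) with ReLU activations and a final
softmax, a few thousand parameters, trainable on CPU in seconds.  It exists so
that the behaviour of the loss functions under class imbalance can be compared
end-to-end; architecture quality is explicitly not the point.

Training mirrors the standard recipe for this problem family: stochastic
gradient descent, reduce-on-plateau learning-rate decay, early stopping on
validation loss, and selection of the weights with the lowest validation loss.
"""

from __future__ import annotations

import gc
from dataclasses import dataclass, field

import numpy as np

from . import _backend as B
from .arrays import one_hot_encode
from .errors import ConfigurationError

__all__ = ["ModelSpec", "TinyConvSegmenter", "TrainingHistory", "train_model"]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and optimisation settings for the tiny segmenter."""

    hidden_channels: int = 8
    kernel_size: int = 3
    learning_rate: float = 0.1   # plain SGD, as in the published recipe
    momentum: float = 0.0
    batch_size: int = 8
    epochs: int = 12
    lr_factor: float = 0.1       # reduce-on-plateau multiplier
    lr_patience: int = 4         # epochs without val improvement before decay
    early_stop_patience: int = 8


class TinyConvSegmenter:
    """Three-layer convolutional softmax segmenter over (B, H, W, 1) images.

    Hidden layers use parameter-free instance normalisation: without it the
    softmax saturates toward the majority class within the first epoch on
    severely imbalanced tasks and gradients vanish irrecoverably.
    """

    def __init__(self, num_classes: int, spec: ModelSpec = ModelSpec(),
                 seed: int = 0):
        if num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")
        self.num_classes = num_classes
        self.spec = spec
        rng = np.random.default_rng(seed)
        k, h = spec.kernel_size, spec.hidden_channels
        shapes = [(k, k, 1, h), (k, k, h, h), (k, k, h, num_classes)]
        self.weights = []
        self.biases = []
        for shape in shapes:
            fan_in = shape[0] * shape[1] * shape[2]
            fan_out = shape[0] * shape[1] * shape[3]
            sd = np.sqrt(2.0 / (fan_in + fan_out))  # Xavier
            self.weights.append(B.Tensor(rng.normal(0.0, sd, size=shape).astype(np.float32)))
            self.biases.append(B.Tensor(np.zeros(shape[-1], dtype=np.float32)))

    @property
    def parameters(self) -> list[B.Tensor]:
        return [*self.weights, *self.biases]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters))

    def forward(self, images: np.ndarray) -> B.Tensor:
        """Class-probability map as a graph node (for training).

        Runs in float32: model-scale arithmetic does not need the float64
        precision the loss contracts are tested at.
        """
        x = B.Tensor(np.asarray(images, dtype=np.float32))
        x = B.relu(B.instance_norm(B.conv2d(x, self.weights[0], self.biases[0])))
        x = B.relu(B.instance_norm(B.conv2d(x, self.weights[1], self.biases[1])))
        x = B.conv2d(x, self.weights[2], self.biases[2])
        return B.softmax(x, axis=-1)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.forward(images).data.astype(np.float64)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(images), axis=-1)

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters]

    def set_state(self, state) -> None:
        for p, s in zip(self.parameters, state):
            p.data = s.copy()


@dataclass
class TrainingHistory:
    epochs_run: int = 0
    train_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)
    diverged: bool = False
    final_train_loss: float = float("nan")
    best_val_loss: float = float("nan")


def train_model(model: TinyConvSegmenter, images: np.ndarray, masks: np.ndarray,
                loss_fn, seed: int = 0, val_images: np.ndarray | None = None,
                val_masks: np.ndarray | None = None) -> TrainingHistory:
    """SGD training with plateau decay and early stopping.

    ``loss_fn(p, y_onehot)`` must accept a Tensor probability map (training
    path) and a numpy one (validation path) — every loss in this package does.
    With a zero epoch budget the model is returned untrained.
    """
    spec = model.spec
    history = TrainingHistory()
    n = images.shape[0]
    y_all = one_hot_encode(masks, model.num_classes).astype(np.float32)
    use_val = val_images is not None and val_masks is not None
    if use_val:
        y_val = one_hot_encode(val_masks, model.num_classes)

    rng = np.random.default_rng(seed)
    lr = spec.learning_rate
    velocity = [np.zeros_like(p.data) for p in model.parameters]
    best_state = model.get_state()
    best_val = np.inf
    stall = 0

    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, spec.batch_size):
            batch = order[start:start + spec.batch_size]
            p = model.forward(images[batch])
            loss = loss_fn(p, y_all[batch])
            value = loss.item()
            if not np.isfinite(value):
                history.diverged = True
                history.final_train_loss = value
                model.set_state(best_state)
                return history
            for param in model.parameters:
                param.grad = None
            loss.backward()
            for param, vel in zip(model.parameters, velocity):
                vel *= spec.momentum
                vel -= lr * param.grad
                param.data = param.data + vel
            epoch_losses.append(value)
        # graph nodes carry reference cycles (node <-> backward closure);
        # collect per epoch to keep the peak footprint flat
        gc.collect()
        history.epochs_run = epoch + 1
        history.train_losses.append(float(np.mean(epoch_losses)))

        if use_val:
            val_loss = float(loss_fn(model.predict_proba(val_images), y_val).value)
        else:
            val_loss = history.train_losses[-1]
        history.val_losses.append(val_loss)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = model.get_state()
            stall = 0
        else:
            stall += 1
            if stall >= spec.early_stop_patience:
                break
            if stall % spec.lr_patience == 0:
                lr *= spec.lr_factor

    model.set_state(best_state)
    history.final_train_loss = (history.train_losses[-1]
                                if history.train_losses else float("nan"))
    history.best_val_loss = best_val if np.isfinite(best_val) else float("nan")
    return history
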