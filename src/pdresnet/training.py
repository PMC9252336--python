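"""Training protocol for the residual gait classifier.

RMSprop optimization with a step learning-rate schedule (initial 1e-3,
multiplied by 1/5 every 10 epochs), mini-batches of 23 with online
random-erasing augmentation, and early stopping with best-state restore.

The two sigmoid output neurons are trained with complementary labels:
neuron 1 carries the positive class, neuron 0 its complement. For each
neuron the degree of correct prediction p' feeds the configured loss
(improved focal by default); the batch loss is the mean over samples and
neurons, matching the per-epoch loss defined as the average of the
per-sample losses.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .losses import LossParams, get_loss
from .network import PDResNet
from .preprocessing import EraseParams, make_batches, random_erase

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "RMSprop",
    "EarlyStopping",
    "lr_at_epoch",
    "train",
    "evaluate_network",
    "set_global_seed",
]

_PCLIP = 1e-7  # numeric floor/ceiling for p' inside the training loss


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer, schedule, batching, early-stopping and seeding settings."""
    initial_lr: float = 1e-3
    decay_factor: float = 0.2
    decay_every: int = 10
    batch_size: int = 23
    max_epochs: int = 100
    patience: int = 5
    monitor: str = "val_loss"       # or "val_accuracy"
    rmsprop_alpha: float = 0.99
    rmsprop_eps: float = 1e-8
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if not self.initial_lr > 0:
            problems.append(f"initial_lr must be > 0, got {self.initial_lr}")
        if not 0.0 < self.decay_factor < 1.0:
            problems.append(f"decay_factor must be in (0, 1), got {self.decay_factor}")
        if self.decay_every < 1:
            problems.append(f"decay_every must be >= 1, got {self.decay_every}")
        if self.batch_size < 1:
            problems.append(f"batch_size must be >= 1, got {self.batch_size}")
        if self.max_epochs < 1:
            problems.append(f"max_epochs must be >= 1, got {self.max_epochs}")
        if self.patience < 1:
            problems.append(f"patience must be >= 1, got {self.patience}")
        if self.monitor not in ("val_loss", "val_accuracy"):
            problems.append(f"monitor must be val_loss or val_accuracy, "
                            f"got {self.monitor!r}")
        if problems:
            raise ValueError("; ".join(problems))


@dataclass
class TrainHistory:
    """Per-epoch training record; column lengths equal ``stopped_epoch``."""
    epoch: list[int] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": self.epoch, "lr": self.lr,
            "train_loss": self.train_loss,
            "train_accuracy": self.train_accuracy,
            "val_loss": self.val_loss, "val_accuracy": self.val_accuracy,
        })


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Step schedule: lr = initial * factor ** floor((epoch - 1) / every)."""
    if epoch < 1:
        raise ValueError(f"epoch must be >= 1, got {epoch}")
    steps = (epoch - 1) // config.decay_every
    return config.initial_lr * config.decay_factor ** steps


class RMSprop:
    """RMSprop without momentum: v <- a v + (1 - a) g^2; w -= lr g / (sqrt(v) + eps)."""

    def __init__(self, parameters, alpha: float = 0.99, eps: float = 1e-8):
        self.parameters = list(parameters)
        self.alpha = alpha
        self.eps = eps
        self.v = [np.zeros_like(p.data) for p in self.parameters]

    def step(self, lr: float) -> None:
        for p, v in zip(self.parameters, self.v):
            g = p.grad
            v *= self.alpha
            v += (1.0 - self.alpha) * g * g
            p.data -= (lr * g / (np.sqrt(v) + self.eps)).astype(p.data.dtype)


class EarlyStopping:
    """Patience-based stopping on a monitored value, tracking the best epoch."""

    def __init__(self, patience: int = 5, mode: str = "min"):
        if mode not in ("min", "max"):
            raise ValueError("mode must be 'min' or 'max'")
        self.patience = patience
        self.mode = mode
        self.best: float | None = None
        self.best_epoch: int | None = None
        self.bad_epochs = 0

    def update(self, value: float, epoch: int) -> bool:
        """Record this epoch's monitored value; returns True on improvement."""
        improved = (self.best is None
                    or (self.mode == "min" and value < self.best)
                    or (self.mode == "max" and value > self.best))
        if improved:
            self.best = value
            self.best_epoch = epoch
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return improved

    @property
    def should_stop(self) -> bool:
        return self.bad_epochs >= self.patience


def _batch_loss_and_grad(q: np.ndarray, y: np.ndarray, loss_fn, grad_fn):
    """Loss over both output neurons and its gradient w.r.t. the scores q."""
    T = np.stack([1.0 - y, y], axis=1).astype(float)
    p_prime = T * q + (1.0 - T) * (1.0 - q)
    pp = np.clip(p_prime, _PCLIP, 1.0)
    loss = float(np.mean(loss_fn(pp)))
    dpp = np.asarray(grad_fn(pp)) / pp.size
    dq = dpp * (2.0 * T - 1.0)
    return loss, dq


def evaluate_network(network: PDResNet, images: np.ndarray, y: np.ndarray,
                     loss_fn, batch_size: int = 64):
    """Evaluation-mode loss, accuracy and positive-class scores."""
    scores = []
    for start in range(0, len(images), batch_size):
        q = network.forward(images[start:start + batch_size], train=False)
        scores.append(np.asarray(q, dtype=float))
    q = np.concatenate(scores, axis=0)
    T = np.stack([1.0 - y, y], axis=1).astype(float)
    pp = np.clip(T * q + (1.0 - T) * (1.0 - q), _PCLIP, 1.0)
    loss = float(np.mean(loss_fn(pp)))
    p_plus = q[:, 1]
    acc = float(np.mean((p_plus >= 0.5).astype(int) == y))
    return loss, acc, p_plus


def train(network: PDResNet, train_images: np.ndarray, train_labels: np.ndarray,
          val_images: np.ndarray, val_labels: np.ndarray,
          config: TrainConfig | None = None, loss: str = "improved_focal",
          loss_params: LossParams | None = None,
          erase_params: EraseParams | None = None
          ) -> tuple[PDResNet, TrainHistory]:
    """Run the full training protocol; returns the best-monitored state.

    Per epoch: shuffle, batch (size ``config.batch_size``), apply random
    erasing online to each training batch, forward, mean loss over the
    batch, RMSprop update at the scheduled learning rate; then evaluate
    the held-out set. Stops when the monitored value fails to improve for
    ``patience`` consecutive epochs or at ``max_epochs``, and restores the
    best recorded network state.
    """
    config = config or TrainConfig()
    config.validate()
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("training and held-out sets must be non-empty")
    y_tr = np.asarray(train_labels, dtype=int)
    y_val = np.asarray(val_labels, dtype=int)
    loss_fn, grad_fn = get_loss(loss, loss_params)

    optimizer = RMSprop(network.parameters(),
                        alpha=config.rmsprop_alpha, eps=config.rmsprop_eps)
    mode = "min" if config.monitor == "val_loss" else "max"
    stopper = EarlyStopping(config.patience, mode)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    best_state = network.state_dict()

    for epoch in range(1, config.max_epochs + 1):
        lr = lr_at_epoch(config, epoch)
        batches = make_batches(np.arange(len(train_images)),
                               config.batch_size, shuffle=True, rng=rng)
        batch_losses, n_correct = [], 0
        for idx in batches:
            xb = train_images[idx]
            if erase_params is not None and erase_params.probability > 0:
                xb = xb.copy()
                for i in range(xb.shape[0]):
                    xb[i, 0] = random_erase(xb[i, 0], erase_params, rng)
            network.zero_grad()
            q = np.asarray(network.forward(xb, train=True), dtype=float)
            batch_loss, dq = _batch_loss_and_grad(q, y_tr[idx], loss_fn, grad_fn)
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            network.backward(dq)
            optimizer.step(lr)
            batch_losses.append(batch_loss)
            n_correct += int(np.sum((q[:, 1] >= 0.5).astype(int) == y_tr[idx]))

        val_loss, val_acc, _ = evaluate_network(network, val_images, y_val, loss_fn)
        history.epoch.append(epoch)
        history.lr.append(lr)
        history.train_loss.append(float(np.mean(batch_losses)))
        history.train_accuracy.append(n_correct / len(train_images))
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)

        monitored = val_loss if config.monitor == "val_loss" else val_acc
        if stopper.update(monitored, epoch):
            best_state = network.state_dict()
        history.stopped_epoch = epoch
        if stopper.should_stop:
            break

    network.load_state_dict(best_state)
    history.best_epoch = stopper.best_epoch or history.stopped_epoch
    return network, history


def set_global_seed(seed: int) -> None:
    """Seed the process-wide RNGs (NumPy legacy and Python's random).

    The package threads explicit generators everywhere, so this is a
    belt-and-braces guard for user code mixing in global-RNG calls.
    """
    np.random.seed(seed % (2 ** 32))
    random.seed(seed)


def derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage 31-bit seeds from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s >> 1) for s in state]
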