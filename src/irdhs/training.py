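"""Training protocol: BCE loss, warmup+cosine LR schedule, early stopping,
class-balanced resampling, and the epoch loop with best-weights restoration.

The schedule increases the learning rate linearly from ``warmup_begin_lr`` to
``max_lr`` over ``warmup_steps`` optimizer steps, then follows a cosine decay
down to ``final_lr`` at ``total_steps``.  Early stopping halts training after
``patience`` consecutive epochs without a strict improvement of the validation
loss; the parameters from the best validation epoch are restored on exit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import AdamW, Module, SGD

BCE_EPS = 1e-7


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = BCE_EPS) -> float:
    """Mean binary cross-entropy of probabilities against {0,1} labels.

    Probabilities are clipped to [eps, 1-eps] before taking logs.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    pc = np.clip(p, eps, 1.0 - eps)
    return float(-(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)).mean())


def bce_grad(p: np.ndarray, y: np.ndarray, eps: float = BCE_EPS) -> np.ndarray:
    """Gradient of mean BCE w.r.t. the probabilities (clipped as in the loss)."""
    pc = np.clip(np.asarray(p, float), eps, 1.0 - eps)
    y = np.asarray(y, dtype=float)
    return (pc - y) / (pc * (1.0 - pc)) / y.size


@dataclass
class SchedulerConfig:
    """Warmup + cosine decay schedule, stepped per optimizer step."""

    warmup_begin_lr: float
    max_lr: float
    final_lr: float
    warmup_steps: int
    total_steps: int

    def __post_init__(self) -> None:
        if not (self.warmup_begin_lr <= self.max_lr):
            raise ValueError("warmup_begin_lr must not exceed max_lr")
        if not (self.final_lr <= self.max_lr):
            raise ValueError("final_lr must not exceed max_lr")
        if not (0 <= self.warmup_steps < self.total_steps):
            raise ValueError("require 0 <= warmup_steps < total_steps")


def lr_at(step: int, cfg: SchedulerConfig) -> float:
    """Learning rate at a given optimizer step under the warmup+cosine rule."""
    if not (0 <= step <= cfg.total_steps):
        raise ValueError(f"step {step} outside [0, {cfg.total_steps}]")
    if step <= cfg.warmup_steps:
        if cfg.warmup_steps == 0:
            return cfg.max_lr
        frac = step / cfg.warmup_steps
        return cfg.warmup_begin_lr + frac * (cfg.max_lr - cfg.warmup_begin_lr)
    decay_frac = (step - cfg.warmup_steps) / (cfg.total_steps - cfg.warmup_steps)
    return cfg.final_lr + 0.5 * (cfg.max_lr - cfg.final_lr) * (
        1.0 + math.cos(math.pi * decay_frac)
    )


class EarlyStopper:
    """Stop after `patience` consecutive epochs without strict improvement.

    Improvement means the validation loss drops below the best seen so far by
    more than ``min_delta`` (default 0, i.e. any strict decrease counts).
    ``best_epoch`` is 1-based.
    """

    def __init__(self, patience: int, min_delta: float = 0.0):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.min_delta = min_delta
        self.best_loss = math.inf
        self.best_epoch = 0
        self.epochs_since_best = 0
        self.epoch = 0

    def update(self, val_loss: float) -> str:
        """Register one epoch's validation loss; returns 'continue' or 'stop'."""
        self.epoch += 1
        if val_loss < self.best_loss - self.min_delta:
            self.best_loss = val_loss
            self.best_epoch = self.epoch
            self.epochs_since_best = 0
            return "continue"
        self.epochs_since_best += 1
        return "stop" if self.epochs_since_best >= self.patience else "continue"


def imbalanced_sampler(
    labels: np.ndarray, seed: int, n_draws: int | None = None
) -> np.ndarray:
    """Class-balanced resampling with replacement.

    Each draw picks an index with per-class probability inversely
    proportional to class frequency, so an epoch is balanced 50/50 in
    expectation regardless of the label imbalance.
    """
    labels = np.asarray(labels)
    classes, inverse = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("imbalanced_sampler requires both classes present")
    if classes.size > 2:
        raise ValueError("binary labels expected")
    n = labels.size if n_draws is None else n_draws
    rng = np.random.default_rng(seed)
    counts = np.bincount(inverse)
    weights = 1.0 / counts[inverse]
    weights /= weights.sum()
    return rng.choice(labels.size, size=n, replace=True, p=weights)


@dataclass
class TrainConfig:
    """Epoch-loop settings (optimizer family, stopping, sampling, seeding)."""

    max_epochs: int = 100
    patience: int = 10
    optimizer: str = "adamw"  # or "sgd_momentum"
    momentum: float = 0.95
    weight_decay: float = 0.01
    batch_size: int = 64
    seed: int = 0
    lr: float = 1e-3  # used only when no scheduler is given
    min_delta: float = 0.0
    balanced_sampling: bool = False
    clip_grad_norm: float | None = 5.0

    def __post_init__(self) -> None:
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.optimizer not in ("adamw", "sgd_momentum"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainHistory:
    """Per-epoch record of the fit: losses, learning rate, stopping info."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "lr": self.lr,
            }
        )


def predict_in_batches(model: Module, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Eval-mode forward pass over X in batches; returns probabilities."""
    was_training = model.training
    model.eval()
    outs = [model.forward(X[i : i + batch_size]) for i in range(0, len(X), batch_size)]
    model.train(was_training)
    return np.concatenate(outs) if outs else np.empty(0)


def make_optimizer(model: Module, tcfg: TrainConfig):
    if tcfg.optimizer == "sgd_momentum":
        return SGD(model.parameters(), lr=tcfg.lr, momentum=tcfg.momentum)
    return AdamW(model.parameters(), lr=tcfg.lr, weight_decay=tcfg.weight_decay)


def _clip_global_norm(model: Module, max_norm: float) -> None:
    """Rescale all gradients so their global L2 norm is at most max_norm."""
    total = math.sqrt(
        sum(float((p.grad**2).sum()) for p in model.parameters() if p.trainable)
    )
    if total > max_norm:
        scale = max_norm / total
        for p in model.parameters():
            if p.trainable:
                p.grad *= scale


def fit(
    model: Module,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    tcfg: TrainConfig,
    scfg: SchedulerConfig | None = None,
) -> TrainHistory:
    """Train `model` with BCE; returns history with best weights restored.

    The model must map an input batch to a probability vector.  Divergence
    (NaN loss) aborts with a diagnostic.  Seeded, hence reproducible: the
    same seed yields identical histories and final parameters.
    """
    X, y = train
    Xv, yv = val
    y = np.asarray(y, dtype=float)
    yv = np.asarray(yv, dtype=float)
    n = len(X)
    opt = make_optimizer(model, tcfg)
    stopper = EarlyStopper(tcfg.patience, tcfg.min_delta)
    history = TrainHistory()
    ss = np.random.SeedSequence(tcfg.seed)
    epoch_seeds = ss.generate_state(tcfg.max_epochs)
    best_state = model.state()
    step = 0

    for epoch in range(1, tcfg.max_epochs + 1):
        epoch_seed = int(epoch_seeds[epoch - 1] % (2**31))
        if tcfg.balanced_sampling:
            order = imbalanced_sampler(y, seed=epoch_seed)
        else:
            order = np.random.default_rng(epoch_seed).permutation(n)
        model.train(True)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            if scfg is not None:
                opt.lr = lr_at(min(step, scfg.total_steps), scfg)
            opt.zero_grad()
            p = model.forward(X[idx])
            loss = bce_loss(p, y[idx])
            if math.isnan(loss):
                raise RuntimeError(
                    f"training diverged: NaN loss at epoch {epoch}, step {step}"
                )
            model.backward(bce_grad(p, y[idx]))
            if tcfg.clip_grad_norm is not None:
                _clip_global_norm(model, tcfg.clip_grad_norm)
            opt.step()
            losses.append(loss)
            step += 1
        val_loss = bce_loss(predict_in_batches(model, Xv), yv)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(val_loss)
        history.lr.append(opt.lr)
        decision = stopper.update(val_loss)
        if stopper.best_epoch == epoch:
            best_state = model.state()
        if decision == "stop":
            break

    model.load_state(best_state)
    model.eval()
    history.best_epoch = stopper.best_epoch
    history.stopped_epoch = stopper.epoch
    return history
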