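"""Classifiers for intron retention.

Two families of scikit-learn-style estimators:

* sequence models over one-hot DHS sequences (``(n, 4, L)`` arrays):
  :class:`BassetClassifier` (conv/pool/dense stack),
  :class:`BasenjiClassifier` (conv tower + residual dilated convolutions +
  attention-pooled head), and :class:`FinetunedSequenceClassifier` (a
  pre-trained convolutional backbone plus a fine-tuning head, optionally
  frozen) — all built on the package's numpy layer engine and therefore
  differentiable w.r.t. the input, which Integrated Gradients needs;

* chromatin-targets models over an ``(n, p)`` matrix of target scores:
  :class:`LogisticTargetsClassifier` (trained with the package's BCE /
  AdamW / class-balanced-sampler protocol; weights used for target ranking)
  and :class:`GBDTTargetsClassifier` (LightGBM at the reference settings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .training import (
    SchedulerConfig,
    TrainConfig,
    fit as train_fit,
    predict_in_batches,
)

TARGET_GROUPS = ("TF", "HM", "ACC")


@dataclass
class TargetsMatrix:
    """n_samples x n_targets chromatin-profile scores with target metadata.

    ``meta`` has one row per target with columns ``name``, ``protein`` and
    ``group``; groups must form a partition over {TF, HM, ACC}.
    """

    values: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x targets)")
        if len(self.meta) != self.values.shape[1]:
            raise ValueError("metadata rows must match the number of targets")
        missing = {"name", "protein", "group"} - set(self.meta.columns)
        if missing:
            raise ValueError(f"metadata missing columns {missing}")
        unknown = set(self.meta["group"]) - set(TARGET_GROUPS)
        if unknown:
            raise ValueError(f"unknown target groups {unknown}")

    @property
    def n_targets(self) -> int:
        return self.values.shape[1]

    def group_sizes(self) -> dict[str, int]:
        counts = self.meta["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in TARGET_GROUPS}


def subset_targets(tm: TargetsMatrix, group: str) -> TargetsMatrix:
    """Column subset by target group; 'ALL' returns the input unchanged."""
    if group == "ALL":
        return tm
    if group not in TARGET_GROUPS:
        raise ValueError(f"unknown group {group!r}; expected ALL/TF/HM/ACC")
    mask = (tm.meta["group"] == group).to_numpy()
    return TargetsMatrix(
        values=tm.values[:, mask], meta=tm.meta.loc[mask].reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# fine-tuning head and backbones


@dataclass
class FinetuneHeadConfig:
    """The fine-tuning block: conv layer, pooling over positions, dense, sigmoid."""

    conv_channels: int = 128
    kernel: int = 8
    dense_units: int = 64
    pooling: str = "attention"  # or "mean"

    def __post_init__(self) -> None:
        if self.pooling not in ("attention", "mean"):
            raise ValueError("pooling must be 'attention' or 'mean'")


def _small_output_init(module: nn.Module) -> nn.Module:
    """Shrink the final dense layer so training starts near chance loss.

    Pooled conv features carry a large common offset (the maximum of
    normalised activations); a full-scale output layer would start the
    sigmoid saturated.
    """
    dense = [m for m in module.walk() if isinstance(m, nn.Dense)]
    if dense:
        dense[-1].W.data *= 0.01
        dense[-1].b.data[...] = 0.0
    return module


def build_finetune_head(
    in_channels: int, cfg: FinetuneHeadConfig, rng: np.random.Generator
) -> nn.Module:
    """Conv -> (attention|mean) pooling -> dense -> sigmoid output."""
    pool: nn.Module = (
        nn.AttentionPool(cfg.conv_channels, rng)
        if cfg.pooling == "attention"
        else nn.MeanPool()
    )
    return _small_output_init(nn.Sequential(
        nn.Conv1d(in_channels, cfg.conv_channels, cfg.kernel, rng),
        nn.GELU(),
        pool,
        nn.Dense(cfg.conv_channels, cfg.dense_units, rng),
        nn.ReLU(),
        nn.Dense(cfg.dense_units, 1, rng),
        nn.Sigmoid(),
        nn.Squeeze(),
    ))


class MiniConvBackbone:
    """Small convolutional backbone satisfying the backbone contract.

    The contract: an object exposing ``build()`` -> a layer module mapping a
    one-hot batch (B, 4, L) to a feature map (B, out_channels, L/downsample),
    deterministic in eval mode and differentiable end-to-end.  Pre-trained
    chromatin models slot in behind the same contract; this default is a
    2-conv-layer miniature used for desk-scale work.
    """

    def __init__(
        self,
        channels: tuple[int, int] = (32, 32),
        kernels: tuple[int, int] = (12, 5),
        pools: tuple[int, int] = (3, 1),
        seed: int = 0,
    ):
        self.channels = channels
        self.kernels = kernels
        self.pools = pools
        self.seed = seed
        self.module_: nn.Module | None = None

    @property
    def out_channels(self) -> int:
        return self.channels[-1]

    @property
    def downsample(self) -> int:
        return int(np.prod([p for p in self.pools if p > 1] or [1]))

    @property
    def receptive_field(self) -> int:
        rf, factor = 1, 1
        for k, p in zip(self.kernels, self.pools):
            rf += (k - 1) * factor
            factor *= p
        return rf

    def build(self) -> nn.Module:
        if self.module_ is None:
            rng = np.random.default_rng(self.seed)
            layers: list[nn.Module] = []
            c_in = 4
            for c, k, p in zip(self.channels, self.kernels, self.pools):
                layers += [nn.Conv1d(c_in, c, k, rng), nn.BatchNorm1d(c), nn.ReLU()]
                if p > 1:
                    layers.append(nn.MaxPool1d(p))
                c_in = c
            self.module_ = nn.Sequential(*layers)
        return self.module_

    def embed(self, X: np.ndarray) -> np.ndarray:
        """Eval-mode feature map for a one-hot batch."""
        module = self.build()
        was = module.training
        module.eval()
        out = module.forward(np.asarray(X, dtype=float))
        module.train(was)
        return out


# ---------------------------------------------------------------------------
# sequence estimators


class _SequenceClassifierBase(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery for the one-hot sequence models."""

    # subclasses implement _build(rng, seq_len) -> nn.Module

    def _validate_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != 4:
            raise ValueError(f"expected one-hot input of shape (n, 4, L), got {X.shape}")
        return X

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            max_epochs=self.max_epochs,
            patience=self.patience,
            optimizer=self.optimizer,
            batch_size=self.batch_size,
            seed=self.seed,
            weight_decay=self.weight_decay,
        )

    def _scheduler(self, n_train: int) -> SchedulerConfig:
        steps_per_epoch = max(1, math.ceil(n_train / self.batch_size))
        total = self.max_epochs * steps_per_epoch
        warmup = min(max(1, int(self.warmup_frac * total)), total - 1)
        return SchedulerConfig(
            warmup_begin_lr=self.max_lr / 25.0,
            max_lr=self.max_lr,
            final_lr=self.max_lr / 50.0,
            warmup_steps=warmup,
            total_steps=total,
        )

    def fit(self, X, y, X_val=None, y_val=None):
        X = self._validate_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("binary classification requires exactly two classes")
        yb = (y == self.classes_[1]).astype(float)
        if X_val is None:
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(len(X))
            n_val = max(1, len(X) // 10)
            val_idx, tr_idx = order[:n_val], order[n_val:]
            X, X_val, yb, y_valb = X[tr_idx], X[val_idx], yb[tr_idx], yb[val_idx]
        else:
            X_val = self._validate_X(X_val)
            y_valb = (np.asarray(y_val) == self.classes_[1]).astype(float)
        build_rng = np.random.default_rng(self.seed)
        self.model_ = self._build(build_rng, seq_len=X.shape[2])
        self.n_parameters_ = self.model_.num_parameters()
        self.history_ = train_fit(
            self.model_, (X, yb), (X_val, y_valb), self._train_config(),
            self._scheduler(len(X)),
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._validate_X(X)
        p = predict_in_batches(self.model_, X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    def value_and_input_grad(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample output probability and its gradient w.r.t. the input.

        Samples in the batch are independent, so one backward pass with a
        unit upstream gradient yields every per-sample input gradient.
        """
        X = self._validate_X(X)
        model = self.model_
        model.eval()
        model.zero_grad()
        p = model.forward(X)
        dx = model.backward(np.ones_like(p))
        model.zero_grad()
        return p, dx


class BassetClassifier(_SequenceClassifierBase):
    """Basset-style CNN: three conv/batch-norm/max-pool layers, three dense.

    Defaults are desk-scale; the pooling factors must divide the sequence
    length at each stage (600 works with the default (3, 4, 5)).
    """

    def __init__(
        self,
        conv_channels=(64, 32, 32),
        conv_kernels=(15, 6, 6),
        pool_sizes=(3, 1, -1),
        dense_units=(32, 16),
        max_epochs: int = 100,
        patience: int = 10,
        optimizer: str = "adamw",
        batch_size: int = 64,
        max_lr: float = 5e-3,
        warmup_frac: float = 0.05,
        weight_decay: float = 0.01,
        seed: int = 0,
    ):
        self.conv_channels = conv_channels
        self.conv_kernels = conv_kernels
        self.pool_sizes = pool_sizes
        self.dense_units = dense_units
        self.max_epochs = max_epochs
        self.patience = patience
        self.optimizer = optimizer
        self.batch_size = batch_size
        self.max_lr = max_lr
        self.warmup_frac = warmup_frac
        self.weight_decay = weight_decay
        self.seed = seed

    def _build(self, rng: np.random.Generator, seq_len: int) -> nn.Module:
        layers: list[nn.Module] = []
        c_in, length = 4, seq_len
        for c, k, p in zip(self.conv_channels, self.conv_kernels, self.pool_sizes):
            layers += [nn.Conv1d(c_in, c, k, rng), nn.BatchNorm1d(c), nn.ReLU()]
            if p == -1:
                p = length  # global pooling over the remaining positions
            if p > 1:
                if length % p:
                    raise ValueError(
                        f"sequence length {length} not divisible by pool size {p}"
                    )
                layers.append(nn.MaxPool1d(p))
                length //= p
            c_in = c
        layers.append(nn.Flatten())
        units = c_in * length
        for d in self.dense_units:
            layers += [nn.Dense(units, d, rng), nn.ReLU()]
            units = d
        layers += [nn.Dense(units, 1, rng), nn.Sigmoid(), nn.Squeeze()]
        return _small_output_init(nn.Sequential(*layers))


class BasenjiClassifier(_SequenceClassifierBase):
    """Basenji-style CNN: linear conv stem, conv-tower blocks pairing linear
    and GELU convolutions, residual dilated convolutions with doubling
    dilation rates, then the attention-pooled fine-tuning head."""

    def __init__(
        self,
        channels: int = 32,
        stem_kernel: int = 12,
        block_kernel: int = 5,
        n_conv_blocks: int = 6,
        pool_factors=(3, 2, 1, 1, 1, 1),
        n_dilated_blocks: int = 3,
        head_channels: int = 64,
        head_kernel: int = 8,
        head_dense_units: int = 64,
        head_pooling: str = "attention",
        max_epochs: int = 100,
        patience: int = 10,
        optimizer: str = "adamw",
        batch_size: int = 64,
        max_lr: float = 5e-3,
        warmup_frac: float = 0.05,
        weight_decay: float = 0.01,
        seed: int = 0,
    ):
        self.channels = channels
        self.stem_kernel = stem_kernel
        self.block_kernel = block_kernel
        self.n_conv_blocks = n_conv_blocks
        self.pool_factors = pool_factors
        self.n_dilated_blocks = n_dilated_blocks
        self.head_channels = head_channels
        self.head_kernel = head_kernel
        self.head_dense_units = head_dense_units
        self.head_pooling = head_pooling
        self.max_epochs = max_epochs
        self.patience = patience
        self.optimizer = optimizer
        self.batch_size = batch_size
        self.max_lr = max_lr
        self.warmup_frac = warmup_frac
        self.weight_decay = weight_decay
        self.seed = seed

    def _build(self, rng: np.random.Generator, seq_len: int) -> nn.Module:
        if len(self.pool_factors) != self.n_conv_blocks:
            raise ValueError("pool_factors must have one entry per conv block")
        c = self.channels
        layers: list[nn.Module] = [nn.Conv1d(4, c, self.stem_kernel, rng)]
        length = seq_len
        for p in self.pool_factors:
            # dual-path block: a linear convolution summed with a
            # batch-normalised GELU convolution over the same input
            layers.append(
                nn.DualPath(
                    nn.Conv1d(c, c, self.block_kernel, rng),
                    nn.Sequential(
                        nn.BatchNorm1d(c),
                        nn.GELU(),
                        nn.Conv1d(c, c, self.block_kernel, rng),
                    ),
                )
            )
            layers.append(nn.BatchNorm1d(c))
            if p > 1:
                if length % p:
                    raise ValueError(
                        f"length {length} not divisible by pool factor {p}"
                    )
                layers.append(nn.MaxPool1d(p))
                length //= p
        for j in range(self.n_dilated_blocks):
            dilation = 2 ** (j + 1)
            layers.append(
                nn.Residual(
                    nn.Sequential(
                        nn.Conv1d(c, c, 3, rng, dilation=dilation),
                        nn.BatchNorm1d(c),
                        nn.GELU(),
                    )
                )
            )
        head_cfg = FinetuneHeadConfig(
            conv_channels=self.head_channels,
            kernel=self.head_kernel,
            dense_units=self.head_dense_units,
            pooling=self.head_pooling,
        )
        layers.append(build_finetune_head(c, head_cfg, rng))
        return nn.Sequential(*layers)


class FinetunedSequenceClassifier(_SequenceClassifierBase):
    """A pre-trained convolutional backbone with a binary head on top.

    ``head='block'`` appends the fine-tuning block (conv + attention pooling
    + dense + sigmoid); ``head='linear'`` merely replaces the classification
    layer (mean-pooled features into one sigmoid unit).  With
    ``freeze_backbone=True`` only the head trains and the backbone
    parameters stay bit-identical.
    """

    def __init__(
        self,
        backbone: MiniConvBackbone | None = None,
        head: str = "block",
        freeze_backbone: bool = False,
        head_channels: int = 64,
        head_kernel: int = 8,
        head_dense_units: int = 64,
        head_pooling: str = "attention",
        max_epochs: int = 100,
        patience: int = 10,
        optimizer: str = "adamw",
        batch_size: int = 64,
        max_lr: float = 5e-3,
        warmup_frac: float = 0.05,
        weight_decay: float = 0.01,
        seed: int = 0,
    ):
        self.backbone = backbone
        self.head = head
        self.freeze_backbone = freeze_backbone
        self.head_channels = head_channels
        self.head_kernel = head_kernel
        self.head_dense_units = head_dense_units
        self.head_pooling = head_pooling
        self.max_epochs = max_epochs
        self.patience = patience
        self.optimizer = optimizer
        self.batch_size = batch_size
        self.max_lr = max_lr
        self.warmup_frac = warmup_frac
        self.weight_decay = weight_decay
        self.seed = seed

    def _build(self, rng: np.random.Generator, seq_len: int) -> nn.Module:
        if self.head not in ("block", "linear"):
            raise ValueError("head must be 'block' or 'linear'")
        backbone = self.backbone if self.backbone is not None else MiniConvBackbone(
            seed=self.seed
        )
        self.backbone_ = backbone
        bb_module = backbone.build()
        if self.freeze_backbone:
            bb_module.freeze()
        c = backbone.out_channels
        if self.head == "linear":
            head_module: nn.Module = nn.Sequential(
                nn.MeanPool(), nn.Dense(c, 1, rng), nn.Sigmoid(), nn.Squeeze()
            )
        else:
            cfg = FinetuneHeadConfig(
                conv_channels=self.head_channels,
                kernel=self.head_kernel,
                dense_units=self.head_dense_units,
                pooling=self.head_pooling,
            )
            head_module = build_finetune_head(c, cfg, rng)
        return nn.Sequential(bb_module, head_module)


def finetune_head(
    backbone: MiniConvBackbone, cfg: FinetuneHeadConfig, seed: int = 0
) -> nn.Module:
    """Compose a backbone with the fine-tuning head into one module."""
    rng = np.random.default_rng(seed)
    return nn.Sequential(
        backbone.build(), build_finetune_head(backbone.out_channels, cfg, rng)
    )


# ---------------------------------------------------------------------------
# targets estimators


class LogisticTargetsClassifier(BaseEstimator, ClassifierMixin):
    """Logistic regression over chromatin-target scores.

    Trained with the package protocol: BCE loss, AdamW with weak decoupled
    L2 (stabilises the weights used for target ranking), warmup+cosine
    schedule, validation-loss early stopping, and the class-balanced
    sampler (the IR classes are heavily imbalanced).  Exposes ``coef_`` and
    ``intercept_`` for the weight-based target ranking.
    """

    def __init__(
        self,
        l2: float = 1e-4,
        max_epochs: int = 1000,
        patience: int = 50,
        batch_size: int = 128,
        max_lr: float = 0.05,
        warmup_frac: float = 0.02,
        seed: int = 0,
    ):
        self.l2 = l2
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.max_lr = max_lr
        self.warmup_frac = warmup_frac
        self.seed = seed

    @staticmethod
    def _matrix(X) -> np.ndarray:
        if isinstance(X, TargetsMatrix):
            X = X.values
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D targets matrix")
        if np.isnan(X).any():
            raise ValueError("targets matrix contains missing values")
        return X

    def fit(self, X, y, X_val=None, y_val=None):
        X = self._matrix(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("labels are constant; need both classes to fit")
        yb = (y == self.classes_[1]).astype(float)
        if X_val is None:
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(len(X))
            n_val = max(1, len(X) // 10)
            val_idx, tr_idx = order[:n_val], order[n_val:]
            X, X_val, yb, y_valb = X[tr_idx], X[val_idx], yb[tr_idx], yb[val_idx]
        else:
            X_val = self._matrix(X_val)
            y_valb = (np.asarray(y_val) == self.classes_[1]).astype(float)

        rng = np.random.default_rng(self.seed)
        model = nn.Sequential(
            nn.Dense(X.shape[1], 1, rng), nn.Sigmoid(), nn.Squeeze()
        )
        tcfg = TrainConfig(
            max_epochs=self.max_epochs,
            patience=self.patience,
            batch_size=self.batch_size,
            seed=self.seed,
            weight_decay=self.l2,
            balanced_sampling=True,
        )
        steps = max(1, math.ceil(len(X) / self.batch_size))
        total = self.max_epochs * steps
        scfg = SchedulerConfig(
            warmup_begin_lr=self.max_lr / 25.0,
            max_lr=self.max_lr,
            final_lr=self.max_lr / 50.0,
            warmup_steps=min(max(1, int(self.warmup_frac * total)), total - 1),
            total_steps=total,
        )
        self.model_ = model
        self.history_ = train_fit(model, (X, yb), (X_val, y_valb), tcfg, scfg)
        dense: nn.Dense = model.modules[0]  # type: ignore[assignment]
        self.coef_ = dense.W.data[:, 0].copy()
        self.intercept_ = float(dense.b.data[0])
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._matrix(X)
        logits = X @ self.coef_ + self.intercept_
        p = 1.0 / (1.0 + np.exp(-logits))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


@dataclass
class GBDTConfig:
    """Gradient-boosted trees at the reference settings."""

    n_estimators: int = 1000
    max_depth: int = -1
    num_leaves: int = 50
    bagging_freq: int = 1
    unbalanced_mode: bool = True


class GBDTTargetsClassifier(BaseEstimator, ClassifierMixin):
    """LightGBM classifier over chromatin-target scores.

    Defaults mirror the reference configuration (1000 trees, unbounded
    depth, 50 leaves, imbalanced mode on); per-feature importances are
    exposed for target ranking.
    """

    def __init__(
        self,
        n_estimators: int = 1000,
        max_depth: int = -1,
        num_leaves: int = 50,
        bagging_freq: int = 1,
        unbalanced_mode: bool = True,
        seed: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.num_leaves = num_leaves
        self.bagging_freq = bagging_freq
        self.unbalanced_mode = unbalanced_mode
        self.seed = seed

    def fit(self, X, y):
        import lightgbm

        X = LogisticTargetsClassifier._matrix(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("labels are constant; need both classes to fit")
        self.booster_ = lightgbm.LGBMClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            num_leaves=self.num_leaves,
            bagging_freq=self.bagging_freq,
            is_unbalance=self.unbalanced_mode,
            random_state=self.seed,
            verbose=-1,
        )
        self.booster_.fit(X, (y == self.classes_[1]).astype(int))
        self.feature_importances_ = np.asarray(
            self.booster_.feature_importances_, dtype=float
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.booster_.predict_proba(LogisticTargetsClassifier._matrix(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]
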