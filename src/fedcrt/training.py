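"""Single-site supervised training: splits, optimisers, and the epoch loop.

Used standalone for the centralized baseline and inside each federated
client.  Reproducibility contract: the per-epoch shuffle and all
augmentation draws derive from ``SeedSequence([cfg.seed, global_epoch])``
where ``global_epoch`` counts epochs across federated rounds via
``epoch_offset`` — so a single federated client trained for R rounds of L
local epochs consumes exactly the same batch order and augmentations as a
centralized run of R*L epochs with the same seed.

The final model is the last epoch's weights (no early stopping or model
selection), validation data never influences the weights, and remainder
batches are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .network import Conv3DNet, ParameterSet
from .preprocess import AugmentationConfig, Patch, augment

__all__ = [
    "TrainConfig",
    "SplitResult",
    "split_cohort",
    "train_local",
    "SGD",
    "Adam",
    "centralized_config",
    "federated_sim_config",
    "federated_real_config",
]


@dataclass
class TrainConfig:
    """Local-training hyperparameters (loss is always cross-entropy)."""

    batch_size: int = 8
    learning_rate: float = 0.001
    optimizer: str = "adam"
    epochs: int = 100
    momentum: float = 0.0  # plain SGD by default
    augmentation: AugmentationConfig | None = None
    seed: int = 0
    class_weighting: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 0 or self.learning_rate < 0:
            raise ValueError("batch_size >= 1, epochs >= 0, learning_rate >= 0 required")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


def centralized_config(**kw) -> TrainConfig:
    """Centralized baseline: batch 8, Adam, lr 0.001, 100 epochs."""
    return TrainConfig(**{"batch_size": 8, "optimizer": "adam", "epochs": 100, **kw})


def federated_sim_config(**kw) -> TrainConfig:
    """Two-client simulation setting: batch 16, plain SGD, lr 0.001."""
    return TrainConfig(**{"batch_size": 16, "optimizer": "sgd", "epochs": 50, **kw})


def federated_real_config(**kw) -> TrainConfig:
    """Three-client setting: batch 16, Adam, lr 0.001."""
    return TrainConfig(**{"batch_size": 16, "optimizer": "adam", "epochs": 50, **kw})


@dataclass
class SplitResult:
    train_ids: list
    val_ids: list


def split_cohort(rows: pd.DataFrame, ratio: float = 0.7, seed: int = 0) -> SplitResult:
    """Stratified 7:3 train/validation split of one site's manifest rows.

    Deterministic given ``seed``; per-class train fraction is within one
    sample of ``ratio``.  A class with fewer than 2 members cannot be
    stratified: a warning is emitted and a plain shuffle split is used.
    """
    if len(rows) < 2:
        raise ValueError("need at least 2 samples to split")
    ids = rows["patient_id"].tolist()
    labels = rows["label"].tolist()
    counts = pd.Series(labels).value_counts()
    stratify = labels
    if len(counts) < 2 or counts.min() < 2:
        warnings.warn("a class has fewer than 2 members; falling back to unstratified split")
        stratify = None
    train_ids, val_ids = train_test_split(
        ids, train_size=ratio, random_state=int(seed) % 2 ** 32, stratify=stratify
    )
    return SplitResult(train_ids=list(train_ids), val_ids=list(val_ids))


class SGD:
    """Plain stochastic gradient descent, optional classical momentum."""

    def __init__(self, lr: float, momentum: float = 0.0):
        self.lr, self.momentum = lr, momentum
        self._vel: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for name, p in params.items():
            g = grads[name]
            if self.momentum:
                v = self._vel.get(name)
                v = self.momentum * v + g if v is not None else g.copy()
                self._vel[name] = v
                g = v
            p -= self.lr * g


class Adam:
    """Adam with bias correction (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for name, p in params.items():
            g = grads[name]
            m = self._m.setdefault(name, np.zeros_like(p))
            v = self._v.setdefault(name, np.zeros_like(p))
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _make_optimizer(cfg: TrainConfig):
    if cfg.optimizer == "sgd":
        return SGD(cfg.learning_rate, cfg.momentum)
    return Adam(cfg.learning_rate)


def _class_weights(y: np.ndarray) -> np.ndarray:
    counts = np.bincount(y, minlength=2).astype(float)
    counts[counts == 0] = 1.0
    return len(y) / (2.0 * counts)


def train_local(
    model: Conv3DNet,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray] | None,
    cfg: TrainConfig,
    epoch_offset: int = 0,
) -> tuple[ParameterSet, pd.DataFrame]:
    """Train a model in place for ``cfg.epochs`` epochs.

    Returns the final weights (a copy) and a per-epoch history frame with
    columns (epoch, train_loss, train_acc, val_loss, val_acc); validation
    columns are NaN when ``val_data`` is None.  Augmentation, when enabled,
    is applied to training samples only.
    """
    x_train, y_train = np.asarray(train_data[0]), np.asarray(train_data[1], dtype=int)
    if len(x_train) == 0:
        raise ValueError("training set is empty")
    opt = _make_optimizer(cfg)
    cw = _class_weights(y_train) if cfg.class_weighting else None
    aug = cfg.augmentation if cfg.augmentation is not None and cfg.augmentation.enabled else None

    records = []
    for e in range(cfg.epochs):
        global_epoch = epoch_offset + e
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), int(global_epoch)]))
        perm = rng.permutation(len(x_train))
        aug_seeds = rng.integers(0, 2 ** 31, size=len(x_train))

        losses, hits, seen = [], 0, 0
        for start in range(0, len(perm), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb = x_train[idx]
            if aug is not None:
                xb = np.stack(
                    [augment(Patch(x), aug, int(s)).data for x, s in zip(xb, aug_seeds[idx])]
                )
            yb = y_train[idx]
            loss = model.loss_and_backward(xb, yb, class_weights=cw)
            opt.step(model.named_parameters(), model.gradients())
            losses.append((loss, len(idx)))
            probs = model.predict_proba(xb)
            hits += int((probs.argmax(axis=1) == yb).sum())
            seen += len(idx)

        train_loss = float(sum(l * n for l, n in losses) / seen)
        rec = {
            "epoch": global_epoch,
            "train_loss": train_loss,
            "train_acc": hits / seen,
            "val_loss": np.nan,
            "val_acc": np.nan,
        }
        if val_data is not None and len(val_data[0]) > 0:
            xv, yv = np.asarray(val_data[0]), np.asarray(val_data[1], dtype=int)
            rec["val_loss"] = model.cross_entropy(xv, yv)
            rec["val_acc"] = float((model.predict_proba(xv).argmax(axis=1) == yv).mean())
        records.append(rec)

    history = pd.DataFrame(
        records, columns=["epoch", "train_loss", "train_acc", "val_loss", "val_acc"]
    )
    return model.get_parameters(), history
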