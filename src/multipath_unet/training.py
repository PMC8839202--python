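"""Training protocol: k-fold cross-validation with early stopping.

Each fold trains a freshly initialized model with Adam (initial learning
rate 1e-4, time-based decay) on the combined Tversky + cross-entropy loss.
Training stops at 200 epochs, or earlier once the epoch-mean training loss
has not improved for 20 consecutive epochs; the per-class validation Dice
similarity coefficient is evaluated after every epoch and its running best
is what the cross-validation aggregates (mean and standard deviation across
folds).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .losses import TverskyParams, combined_loss_and_grad, per_class_dice
from .model import ModelConfig, MultiPathUNet, build_multipath_unet, predict_mask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of sample indices to validation folds."""

    fold_assignments: np.ndarray  # fold id per sample index
    k: int
    seed: int

    def validation_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments == fold)

    def training_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments != fold)


def make_cv_folds(n: int, k: int, seed: int = 0) -> FoldPlan:
    """Random equally-sized validation folds (sizes differ by at most one
    when k does not divide n); deterministic for a fixed seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    assignments = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        assignments[chunk] = fold
    return FoldPlan(fold_assignments=assignments, k=k, seed=seed)


def time_decay_lr(initial: float, decay: float, epoch: int) -> float:
    """Time-based decay schedule: initial / (1 + decay * epoch)."""
    return initial / (1.0 + decay * epoch)


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults follow the published protocol (Adam at 1e-4, 200-epoch cap,
    patience 20); the decay constant defaults to initial_lr * 50 so the
    final-epoch rate stays within ~10% of the initial one.
    """

    initial_lr: float = 1e-4
    lr_decay: float | None = None   # defaults to 5e-4 (~9% decay by epoch 200)
    max_epochs: int = 200
    patience: int = 20
    min_improvement: float = 1e-6
    batch_size: int = 2
    threshold: float = 0.5
    tversky: TverskyParams = field(default_factory=TverskyParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_decay is None:
            # 1/(1 + 5e-4 * 200) = 1/1.1: about 9% total reduction, keeping
            # the final rate close to the initial one
            self.lr_decay = 5e-4
        if self.max_epochs < 1 or self.patience < 0:
            raise ValueError("invalid epoch/patience settings")


@dataclass
class TrainState:
    """Outcome of one training run."""

    epoch: int = 0
    learning_rate: float = 0.0
    best_train_loss: float = float("inf")
    epochs_since_improvement: int = 0
    best_val_dsc_per_class: np.ndarray | None = None
    best_epoch: int = 0
    history: list[dict] = field(default_factory=list)


def train_fold(model: MultiPathUNet, train_data, val_data,
               cfg: TrainConfig) -> TrainState:
    """Train one model on one fold and track the best validation DSC.

    ``train_data`` and ``val_data`` are ``(X, Y)`` pairs with X of shape
    (N, C, H, W) and Y integer labels of shape (N, H, W).
    """
    x_train, y_train = train_data
    x_val, y_val = val_data
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("train and validation sets must be nonempty")
    num_classes = model.config.num_classes
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.initial_lr)
    state = TrainState(best_val_dsc_per_class=np.zeros(num_classes))
    best_mean_dsc = -1.0

    for epoch in range(1, cfg.max_epochs + 1):
        lr = time_decay_lr(cfg.initial_lr, cfg.lr_decay, epoch - 1)
        order = rng.permutation(len(x_train))
        total, seen = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            opt.zero_grad()
            probs = model.forward(x_train[idx], training=True, rng=rng)
            loss, dprobs = combined_loss_and_grad(probs, y_train[idx],
                                                  cfg.tversky)
            model.backward(dprobs)
            opt.step(lr)
            total += loss * len(idx)
            seen += len(idx)
        epoch_loss = total / seen

        val_dsc = evaluate_dsc(model, x_val, y_val, threshold=cfg.threshold,
                               batch_size=cfg.batch_size)
        state.best_val_dsc_per_class = np.maximum(
            state.best_val_dsc_per_class, val_dsc)
        if float(val_dsc.mean()) > best_mean_dsc:
            best_mean_dsc = float(val_dsc.mean())
            state.best_epoch = epoch

        if epoch_loss < state.best_train_loss - cfg.min_improvement:
            state.best_train_loss = epoch_loss
            state.epochs_since_improvement = 0
        else:
            state.epochs_since_improvement += 1
        state.epoch = epoch
        state.learning_rate = lr
        state.history.append({"epoch": epoch, "train_loss": epoch_loss,
                              "lr": lr,
                              "val_dsc": [float(v) for v in val_dsc]})
        logger.info("epoch %d: loss %.5f, val DSC %s", epoch, epoch_loss,
                    np.round(val_dsc, 4))
        if state.epochs_since_improvement >= cfg.patience:
            break
    return state


def evaluate_dsc(model: MultiPathUNet, x: np.ndarray, y: np.ndarray,
                 threshold: float = 0.5, batch_size: int = 4) -> np.ndarray:
    """Per-class DSC on a set, pooling pixel counts over all images."""
    probs = model.predict_proba(x, batch_size=batch_size)
    mask = predict_mask(probs, threshold)
    return per_class_dice(mask, y, num_classes=model.config.num_classes)


@dataclass
class CvResult:
    """Aggregated cross-validation outcome."""

    fold_dsc: np.ndarray       # (k, num_classes) best DSC per fold/class
    fold_states: list[TrainState]
    plan: FoldPlan
    fold_models: list[MultiPathUNet] | None = None

    @property
    def mean_per_class(self) -> np.ndarray:
        return self.fold_dsc.mean(axis=0)

    @property
    def std_per_class(self) -> np.ndarray:
        return self.fold_dsc.std(axis=0)

    @property
    def mean_across_classes(self) -> float:
        return float(self.fold_dsc.mean())

    def to_frame(self) -> pd.DataFrame:
        k, c = self.fold_dsc.shape
        df = pd.DataFrame(self.fold_dsc,
                          columns=[f"dsc_class_{j}" for j in range(c)])
        df.insert(0, "fold", np.arange(k))
        return df

    def to_dict(self) -> dict:
        return {
            "per_fold": self.fold_dsc.tolist(),
            "mean_per_class": self.mean_per_class.tolist(),
            "std_per_class": self.std_per_class.tolist(),
            "mean_across_classes": self.mean_across_classes,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def cross_validate(x: np.ndarray, y: np.ndarray, model_config: ModelConfig,
                   train_config: TrainConfig, k: int = 5, seed: int = 0,
                   keep_models: bool = False) -> CvResult:
    """k-fold cross-validation with a fresh model per fold.

    With ``keep_models`` the trained per-fold models are kept on the result
    so held-out predictions (e.g. colony counts) can be derived afterwards.
    """
    n = len(x)
    plan = make_cv_folds(n, k, seed)
    fold_dsc, states, models = [], [], []
    for fold in range(k):
        tr = plan.training_indices(fold)
        va = plan.validation_indices(fold)
        cfg_f = ModelConfig.from_dict(
            {**model_config.to_dict(), "seed": model_config.seed + fold})
        model = build_multipath_unet(cfg_f)
        tcfg = TrainConfig(**{**train_config.__dict__,
                              "seed": train_config.seed + fold})
        logger.info("fold %d: train %d, val %d", fold, len(tr), len(va))
        state = train_fold(model, (x[tr], y[tr]), (x[va], y[va]), tcfg)
        fold_dsc.append(state.best_val_dsc_per_class)
        states.append(state)
        if keep_models:
            models.append(model)
    return CvResult(fold_dsc=np.array(fold_dsc), fold_states=states,
                    plan=plan, fold_models=models if keep_models else None)
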