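"""Objective, optimizer schedule, early stopping and cross-validation.

The training objective is ``Loss = Loss_ce + lambda_gsc * Loss_gsc``:
multiclass cross-entropy on the predicted class probabilities plus the
gene-subset-consistency penalty ``mean_n sum_{v in Sn} eps(v)(1 - e(v))``,
which pulls the trainable importance vector toward genes with strong prior
disease association.  Note the symbol collision in the field's notation:
the *importance vector* over genes and the *loss weight* are both called
lambda; here they are ``lambda_imp`` (see sortpool) and ``lambda_gsc``.

Optimization is Adam with the learning rate halved every
``lr_halving_epochs`` epochs and early stopping on validation accuracy
(strict improvement required; the best-validation checkpoint is restored).
Cross-validation is stratified K-fold; each sample is tested exactly once
and accuracy plus macro-F1 are reported per fold and as mean +/- sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._autodiff import Adam, Tensor
from .cohort_io import GdaTable, Sample, SignalingCohort
from .model import ModelConfig, PathFormerModel

__all__ = [
    "TrainConfig",
    "cross_entropy_loss",
    "gsc_loss",
    "total_loss",
    "train_model",
    "evaluate",
    "cross_validate",
    "CVResult",
]


@dataclass
class TrainConfig:
    lr: float = 0.001
    lr_halving_epochs: int = 30
    patience: int = 5
    max_epochs: int = 200
    lambda_gsc: float = 0.1
    k: int = 100
    batch_size: int = 32
    seed: int = 0
    folds: int = 5
    val_fraction: float = 0.1

    def validate(self) -> None:
        for name in ("lr", "lr_halving_epochs", "patience", "max_epochs", "k", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lambda_gsc < 0:
            raise ValueError("lambda_gsc must be non-negative")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate for 1-based `epoch`: halved every lr_halving_epochs."""
    return cfg.lr * 0.5 ** (epoch // cfg.lr_halving_epochs)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

_LOG_CLAMP = 1e-12


def cross_entropy_loss(probs: Tensor | np.ndarray, labels: Sequence[int]) -> Tensor:
    """Mean multiclass cross-entropy, -1/N sum_n log p_n[y_n] (clamped log)."""
    if not isinstance(probs, Tensor):
        probs = Tensor(probs)
    labels = np.asarray(labels, dtype=int)
    n, c = probs.shape
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError("label out of range")
    picked = probs[np.arange(n), labels]
    return -(picked + _LOG_CLAMP).log().mean()


def gsc_loss(model: PathFormerModel, samples: list[Sample]) -> Tensor:
    """Gene-subset-consistency loss; always in [0, 1]."""
    return model.gsc_terms(samples)


def total_loss(ce: Tensor, gsc: Tensor, lambda_gsc: float) -> Tensor:
    return ce + lambda_gsc * gsc


# ---------------------------------------------------------------------------
# harness
# ---------------------------------------------------------------------------


def evaluate(model: PathFormerModel, samples: list[Sample]) -> tuple[float, float]:
    """(accuracy, macro-F1) of the model on `samples`."""
    model.eval()
    pred = model.predict(samples)
    y = np.array([s.label for s in samples])
    acc = float(np.mean(pred == y))
    f1 = float(f1_score(y, pred, average="macro", zero_division=0))
    return acc, f1


def train_model(
    cohort: SignalingCohort,
    gda: GdaTable,
    config: TrainConfig,
    model_cfg: ModelConfig | None = None,
    samples: list[Sample] | None = None,
) -> tuple[PathFormerModel, list[dict]]:
    """Train on `samples` (default: the whole cohort) with early stopping.

    A stratified 90/10 train/validation split is carved out of the provided
    samples; the expression transform is fit on the training portion only.
    Returns the model restored to its best-validation checkpoint and the
    per-epoch history (train loss, validation accuracy, learning rate).
    """
    config.validate()
    if samples is None:
        samples = list(cohort.samples)
    labels = [s.label for s in samples]
    if len(set(labels)) < 2:
        raise ValueError("training set contains a single class")

    model_cfg = replace(model_cfg or ModelConfig(), k=config.k, seed=config.seed)
    tr_idx, va_idx = train_test_split(
        np.arange(len(samples)),
        test_size=config.val_fraction,
        stratify=labels,
        random_state=config.seed % (2**31),
    )
    train_samples = [samples[i] for i in tr_idx]
    val_samples = [samples[i] for i in va_idx]

    model = PathFormerModel(cohort, gda, model_cfg)
    model.transform.fit(train_samples)
    opt = Adam(model.parameters().values(), lr=config.lr)
    rng = np.random.default_rng(config.seed)

    best_state = model.state_copy()
    best_val = -np.inf
    since_improve = 0
    history: list[dict] = []

    for epoch in range(1, config.max_epochs + 1):
        opt.lr = lr_at_epoch(config, epoch)
        model.train()
        order = rng.permutation(len(train_samples))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = [train_samples[i] for i in order[start : start + config.batch_size]]
            opt.zero_grad()
            probs, _, _ = model.forward_batch(batch)
            ce = cross_entropy_loss(probs, [s.label for s in batch])
            gsc = model.gsc_terms(batch)
            loss = total_loss(ce, gsc, config.lambda_gsc)
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(batch)
        epoch_loss /= len(train_samples)

        val_acc, _ = evaluate(model, val_samples)
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss, "val_acc": val_acc, "lr": opt.lr}
        )
        if val_acc > best_val:  # strict: ties keep the earlier checkpoint
            best_val = val_acc
            best_state = model.state_copy()
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                break

    model.load_state(best_state)
    model.eval()
    return model, history


@dataclass
class CVResult:
    fold_accuracy: list[float]
    fold_f1: list[float]
    models: list[PathFormerModel] = field(repr=False, default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracy))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.fold_f1))

    @property
    def sd_f1(self) -> float:
        return float(np.std(self.fold_f1))


def cross_validate(
    cohort: SignalingCohort,
    gda: GdaTable,
    config: TrainConfig,
    model_cfg: ModelConfig | None = None,
    keep_models: bool = False,
) -> CVResult:
    """Stratified K-fold cross-validation; metrics computed on test folds only."""
    config.validate()
    y = cohort.labels()
    counts = np.bincount(y)
    if counts.min() < config.folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than {config.folds} folds"
        )
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed % (2**31))
    result = CVResult(fold_accuracy=[], fold_f1=[])
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold_cfg = replace(config, seed=config.seed + fold)
        model, _ = train_model(
            cohort,
            gda,
            fold_cfg,
            model_cfg=model_cfg,
            samples=[cohort.samples[i] for i in tr],
        )
        acc, f1 = evaluate(model, [cohort.samples[i] for i in te])
        result.fold_accuracy.append(acc)
        result.fold_f1.append(f1)
        if keep_models:
            result.models.append(model)
    return result
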