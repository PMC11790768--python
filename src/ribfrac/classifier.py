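"""Patch classifier: architecture, two-phase training schedule, prediction.

The model is a convolutional backbone followed by the classification head
used throughout this package: two dense layers of 198 units each, a dropout
layer (rate 0.5) and the final class layer, trained with categorical
cross-entropy and Adam at batch size 16.

Training is transfer-learning style in two phases: phase 1 freezes the
backbone and fits only the head (learning rate 1e-4); phase 2 unfreezes
everything and fine-tunes end to end at a lower rate (8e-5). Both phases run
early stopping on the validation loss (patience 15, best weights restored)
and reduce the learning rate by a configurable factor when the validation
loss plateaus (patience 2). Validation macro-F1 over the terminal classes is
recorded per epoch and drives hyperparameter selection across CV folds.

Two backbones are available: ``small_convnet``, a compact CPU-friendly net
that trains in seconds and is the default, and ``residual``, a deeper
randomly-initialized residual-block backbone. Patches enter natively at
99x99, single channel, scaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import f1_score

from . import nn
from .errors import ConfigError, DataError
from .labels import CLASSES, label_index
from .mining import PatchSample
from .partition import GroupedDataset, check_no_leakage

BACKBONES = ("small_convnet", "residual")


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "small_convnet"
    n_classes: int = 5
    dense_units: tuple[int, int] = (198, 198)
    dropout_rate: float = 0.5
    batch_size: int = 16
    patch_size: int = 99

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ConfigError(f"unknown backbone {self.backbone!r}; expected one of {BACKBONES}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must lie in [0, 1)")
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")


@dataclass(frozen=True)
class PhaseSpec:
    frozen_backbone: bool
    lr: float
    max_epochs: int = 100

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ConfigError("learning rate must be positive")
        if self.max_epochs < 1:
            raise ConfigError("max_epochs must be >= 1")


@dataclass(frozen=True)
class TrainSchedule:
    phase1: PhaseSpec = field(default_factory=lambda: PhaseSpec(True, 1e-4, 100))
    phase2: PhaseSpec = field(default_factory=lambda: PhaseSpec(False, 8e-5, 100))
    early_stop_patience: int = 15
    plateau_patience: int = 2
    plateau_factor: float = 0.1

    def __post_init__(self) -> None:
        if self.early_stop_patience < 1 or self.plateau_patience < 1:
            raise ConfigError("patience values must be >= 1")
        if not 0.0 < self.plateau_factor < 1.0:
            raise ConfigError("plateau_factor must lie in (0, 1)")


@dataclass
class LogitRecord:
    """Per-patch prediction: the pre-softmax score vector and its argmax."""

    sample: PatchSample
    true_label: int
    predicted_label: int
    scores: np.ndarray


class PatchClassifier:
    """Backbone + dense head with explicit freeze control."""

    def __init__(self, backbone: nn.Sequential, head: nn.Sequential, config: ModelConfig):
        self.backbone = backbone
        self.head = head
        self.config = config
        self.backbone_frozen = False

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        return self.head.forward(self.backbone.forward(x, train=train, rng=rng), train=train, rng=rng)

    def backward(self, grad: np.ndarray) -> None:
        grad = self.head.backward(grad)
        if not self.backbone_frozen:
            self.backbone.backward(grad)

    def all_params(self) -> list[nn.Param]:
        return self.backbone.params() + self.head.params()

    def trainable_params(self) -> list[nn.Param]:
        return self.head.params() if self.backbone_frozen else self.all_params()

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.all_params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.all_params()
        if len(weights) != len(params):
            raise DataError("weight list does not match the model's parameters")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise DataError("weight shape mismatch")
            p.value[...] = w

    def predict_scores(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        outs = [self.forward(x[i : i + batch]) for i in range(0, len(x), batch)]
        return np.concatenate(outs, axis=0)


def _build_backbone(name: str, rng: np.random.Generator) -> tuple[nn.Sequential, int]:
    """Backbone plus its flattened feature dimension for a 99x99 input."""
    if name == "small_convnet":
        layers = [
            nn.AvgPool(3),        # 99 -> 33
            nn.Conv2D(1, 8, 3, rng),   # -> 31
            nn.ReLU(),
            nn.MaxPool2(),        # -> 15
            nn.Conv2D(8, 16, 3, rng),  # -> 13
            nn.ReLU(),
            nn.MaxPool2(),        # -> 6
            nn.Flatten(),
        ]
        return nn.Sequential(layers), 16 * 6 * 6
    if name == "residual":
        layers = [
            nn.AvgPool(3),              # 99 -> 33
            nn.Conv2D(1, 16, 3, rng, pad=1),
            nn.ReLU(),
            nn.Residual(16, rng),
            nn.MaxPool2(),              # -> 16
            nn.Residual(16, rng),
            nn.MaxPool2(),              # -> 8
            nn.Conv2D(16, 32, 3, rng),  # -> 6
            nn.ReLU(),
            nn.MaxPool2(),              # -> 3
            nn.Flatten(),
        ]
        return nn.Sequential(layers), 32 * 3 * 3
    raise ConfigError(f"unknown backbone {name!r}")


def build_model(cfg: ModelConfig, seed: int = 0) -> PatchClassifier:
    """Construct the (seeded, randomly initialized) patch classifier."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xB00]))
    backbone, feat = _build_backbone(cfg.backbone, rng)
    u1, u2 = cfg.dense_units
    head = nn.Sequential(
        [
            nn.Dense(feat, u1, rng),
            nn.ReLU(),
            nn.Dense(u1, u2, rng),
            nn.ReLU(),
            nn.Dropout(cfg.dropout_rate),
            nn.Dense(u2, cfg.n_classes, rng),
        ]
    )
    return PatchClassifier(backbone, head, cfg)


def dataset_arrays(ds: GroupedDataset | Sequence[PatchSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack patches into (N, 1, H, W) float32 in [0, 1] plus label indices."""
    samples = ds.samples if isinstance(ds, GroupedDataset) else list(ds)
    if not samples:
        raise DataError("empty sample set")
    x = np.stack([s.patch for s in samples]).astype(np.float32) / 255.0
    y = np.array([label_index(s.label) for s in samples], dtype=np.int64)
    return x[:, None, :, :], y


def _eval_loss_f1(
    model: PatchClassifier,
    feats_or_x: np.ndarray,
    y: np.ndarray,
    head_only: bool,
    batch: int = 256,
) -> tuple[float, float]:
    outs = []
    for i in range(0, len(y), batch):
        xb = feats_or_x[i : i + batch]
        outs.append(model.head.forward(xb) if head_only else model.forward(xb))
    logits = np.concatenate(outs, axis=0)
    loss, _ = nn.softmax_cross_entropy(logits, y)
    preds = logits.argmax(axis=1)
    f1 = float(f1_score(y, preds, average="macro", zero_division=0))
    return loss, f1


def train_two_phase(
    model: PatchClassifier,
    fit: GroupedDataset,
    val: GroupedDataset,
    schedule: TrainSchedule = TrainSchedule(),
    seed: int = 0,
) -> tuple[PatchClassifier, list[dict]]:
    """Run the freeze-then-finetune schedule; returns the model and history.

    Each phase: minibatch Adam updates, per-epoch validation loss and
    macro-F1, plateau-triggered learning-rate decay, early stopping on the
    validation loss, and restoration of the best-validation-loss weights at
    phase end. Phase 1 leaves every backbone weight bit-identical. The
    history holds one entry per epoch with phase, losses, F1 and the
    learning rate in force during that epoch.
    """
    if len(fit) == 0 or len(val) == 0:
        raise DataError("fit and validation sets must be non-empty")
    check_no_leakage(fit, val)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x7124]))
    x_fit, y_fit = dataset_arrays(fit)
    x_val, y_val = dataset_arrays(val)
    bs = model.config.batch_size
    history: list[dict] = []

    for phase_no, phase in ((1, schedule.phase1), (2, schedule.phase2)):
        model.backbone_frozen = phase.frozen_backbone
        opt = nn.Adam(model.trainable_params(), phase.lr)
        if phase.frozen_backbone:
            # Frozen backbone: features are constant, compute them once.
            fit_in = model.backbone.forward(x_fit)
            val_in = model.backbone.forward(x_val)
        else:
            fit_in, val_in = x_fit, x_val

        best_loss = np.inf
        best_weights = model.get_weights()
        lr = phase.lr
        epochs_since_best = 0
        epochs_since_drop = 0
        for epoch in range(1, phase.max_epochs + 1):
            order = rng.permutation(len(y_fit))
            batch_losses = []
            for start in range(0, len(order), bs):
                idx = order[start : start + bs]
                xb, yb = fit_in[idx], y_fit[idx]
                logits = (
                    model.head.forward(xb, train=True, rng=rng)
                    if phase.frozen_backbone
                    else model.forward(xb, train=True, rng=rng)
                )
                loss, grad = nn.softmax_cross_entropy(logits, yb)
                batch_losses.append(loss)
                if phase.frozen_backbone:
                    model.head.backward(grad)
                else:
                    model.backward(grad)
                opt.step()
            val_loss, val_f1 = _eval_loss_f1(
                model, val_in, y_val, head_only=phase.frozen_backbone
            )
            history.append(
                {
                    "phase": phase_no,
                    "epoch": epoch,
                    "train_loss": float(np.mean(batch_losses)),
                    "val_loss": val_loss,
                    "val_f1": val_f1,
                    "lr": lr,
                }
            )
            if val_loss < best_loss - 1e-9:
                best_loss = val_loss
                best_weights = model.get_weights()
                epochs_since_best = 0
                epochs_since_drop = 0
            else:
                epochs_since_best += 1
                epochs_since_drop += 1
                if epochs_since_drop >= schedule.plateau_patience:
                    lr *= schedule.plateau_factor
                    opt.lr = lr
                    epochs_since_drop = 0
                if epochs_since_best >= schedule.early_stop_patience:
                    break
        model.set_weights(best_weights)
    model.backbone_frozen = False
    return model, history


def predict_logits(
    model: PatchClassifier, samples: Sequence[PatchSample] | GroupedDataset
) -> list[LogitRecord]:
    """One record per sample, in input order: pre-softmax scores plus the
    argmax label (ties break toward the lowest class index)."""
    sample_list = samples.samples if isinstance(samples, GroupedDataset) else list(samples)
    x, y = dataset_arrays(sample_list)
    scores = model.predict_scores(x)
    return [
        LogitRecord(
            sample=s,
            true_label=int(t),
            predicted_label=int(np.argmax(row)),
            scores=row.astype(np.float64),
        )
        for s, t, row in zip(sample_list, y, scores)
    ]


@dataclass
class CVCandidate:
    """One hyperparameter configuration with its per-fold training histories."""

    config: object
    fold_histories: list[list[dict] | None]


def select_hyperparameters(cv_results: Sequence[CVCandidate]) -> object:
    """Pick the configuration with the best mean best-epoch validation F1.

    Per fold, the best epoch is the one with the highest validation macro-F1
    (first occurrence). Candidates with any failed fold (missing or empty
    history) are disqualified. Ties break toward fewer epochs-to-best, then
    candidate order.
    """
    if not cv_results:
        raise DataError("no CV results to select from")
    scored = []
    for pos, cand in enumerate(cv_results):
        if not cand.fold_histories or any(not h for h in cand.fold_histories):
            continue
        best_f1s, best_epochs = [], []
        for hist in cand.fold_histories:
            f1s = [e["val_f1"] for e in hist]
            i = int(np.argmax(f1s))
            best_f1s.append(f1s[i])
            best_epochs.append(i + 1)
        scored.append((-float(np.mean(best_f1s)), float(np.mean(best_epochs)), pos, cand.config))
    if not scored:
        raise DataError("every candidate had a failed fold")
    scored.sort(key=lambda t: t[:3])
    return scored[0][3]
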