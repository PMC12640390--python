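"""Training loop: Adam, plateau learning-rate schedule, best-checkpoint keeping."""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ..metrics import inverse_class_frequency_weights
from ..synthetic import split_videos
from ..time_encoding import encode_time
from .data import FrameDataset
from .models import (
    FusedStageClassifier,
    ModelConfig,
    StageClassifier,
    build_model,
    combined_loss,
)
from . import autograd as ag
from .preprocess import AugmentationPolicy, augment, preprocess_image

__all__ = ["TrainConfig", "Adam", "train", "predict_probabilities", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    initial_lr: float = 0.001
    batch_size: int = 32
    lr_factor: float = 0.1
    lr_patience: int = 3
    min_lr: float = 1e-6
    class_weighting: str = "inverse"  # or "none"
    seed: int = 0
    augmentation: AugmentationPolicy | None = None


class Adam:
    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _Plateau:
    """Reduce lr by ``factor`` after ``patience`` epochs without val-loss improvement."""

    def __init__(self, optimizer: Adam, factor: float, patience: int, min_lr: float):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad = 0

    def step(self, val_loss: float) -> None:
        if val_loss < self.best - 1e-8:
            self.best = val_loss
            self.bad = 0
        else:
            self.bad += 1
            if self.bad > self.patience:
                self.opt.lr = max(self.min_lr, self.opt.lr * self.factor)
                self.bad = 0


def _prepare_inputs(
    dataset: FrameDataset, image_size: int, policy: AugmentationPolicy | None,
    rng: np.random.Generator | None,
) -> np.ndarray:
    out = np.empty((len(dataset), 3, image_size, image_size))
    for i, img in enumerate(dataset.images):
        frame = augment(img, policy, rng) if policy is not None else img
        out[i] = preprocess_image(frame, image_size)
    return out


def _time_vectors(minutes: np.ndarray) -> np.ndarray:
    return np.stack([encode_time(m) for m in minutes])


def _forward_loss(model, x, tvec, y, weights):
    if isinstance(model, FusedStageClassifier):
        l1, l2 = model(x, tvec)
        return combined_loss(l1, l2, y, weights), l2.data
    logits = model(x)
    return ag.cross_entropy(logits, y, weights), logits.data


def train(
    dataset: FrameDataset,
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
) -> tuple[StageClassifier | FusedStageClassifier, pd.DataFrame]:
    """Train on a video-level 70/10/20 split of ``dataset``.

    Returns the best-validation-loss model state and a per-epoch history
    (train loss, validation loss, validation accuracy, learning rate).
    Deterministic for a given ``train_config.seed``.
    """
    cfg = train_config or TrainConfig()
    if model_config.num_classes != len(dataset.label_names):
        raise ValueError(
            f"model has {model_config.num_classes} classes but dataset defines "
            f"{len(dataset.label_names)}"
        )
    rng = np.random.default_rng(cfg.seed)
    split = split_videos(sorted(set(dataset.video_ids)), seed=rng)
    part = np.array([split[v] for v in dataset.video_ids])
    train_idx = np.flatnonzero(part == "train")
    val_idx = np.flatnonzero(part == "val")
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("empty training or validation split")

    model = build_model(model_config, seed=cfg.seed)
    history_rows: list[dict] = []
    if cfg.epochs == 0:
        return model, pd.DataFrame(history_rows)

    y = dataset.labels
    weights = None
    if cfg.class_weighting == "inverse":
        counts = np.bincount(y[train_idx], minlength=model_config.num_classes)
        weights = np.ones(model_config.num_classes)
        present = counts > 0
        if not present.all():
            missing = [dataset.label_names[i] for i in np.flatnonzero(~present)]
            warnings.warn(
                f"classes absent from the training split get unit weight: {missing}",
                stacklevel=2,
            )
        weights[present] = inverse_class_frequency_weights(counts[present])

    aug_rng = np.random.default_rng(rng.integers(2**63))
    x_val = _prepare_inputs(dataset.subset(val_idx), model_config.image_size, None, None)
    t_val = _time_vectors(dataset.minutes[val_idx]) if model_config.fused else None
    x_train_clean = None
    if cfg.augmentation is None:
        x_train_clean = _prepare_inputs(
            dataset.subset(train_idx), model_config.image_size, None, None
        )
    t_train = _time_vectors(dataset.minutes[train_idx]) if model_config.fused else None

    opt = Adam(model.parameters(), lr=cfg.initial_lr)
    sched = _Plateau(opt, cfg.lr_factor, cfg.lr_patience, cfg.min_lr)
    best_loss = np.inf
    best_state = model.state_arrays()

    for epoch in range(cfg.epochs):
        if cfg.augmentation is not None:
            x_train = _prepare_inputs(
                dataset.subset(train_idx), model_config.image_size, cfg.augmentation, aug_rng
            )
        else:
            x_train = x_train_clean
        order = rng.permutation(len(train_idx))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            model.zero_grad()
            loss, _ = _forward_loss(
                model,
                x_train[batch],
                None if t_train is None else t_train[batch],
                y[train_idx][batch],
                weights,
            )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))

        val_loss, val_logits = _forward_loss(
            model, x_val, t_val, y[val_idx], weights
        )
        val_loss = float(val_loss.data)
        val_acc = float(np.mean(np.argmax(val_logits, axis=1) == y[val_idx]))
        sched.step(val_loss)
        history_rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
                "val_accuracy": val_acc,
                "lr": opt.lr,
            }
        )
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_arrays()

    model.load_state_arrays(best_state)
    return model, pd.DataFrame(history_rows)


def predict_probabilities(
    model: StageClassifier | FusedStageClassifier,
    dataset: FrameDataset,
    batch_size: int = 64,
) -> np.ndarray:
    """Per-frame class probabilities (softmax of the inference head)."""
    size = model.config.image_size
    fused = isinstance(model, FusedStageClassifier)
    tvecs = _time_vectors(dataset.minutes) if fused else None
    out = []
    for start in range(0, len(dataset), batch_size):
        idx = np.arange(start, min(start + batch_size, len(dataset)))
        x = _prepare_inputs(dataset.subset(idx), size, None, None)
        logits = (
            model.predict_logits(x, tvecs[idx]) if fused else model.predict_logits(x)
        )
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        out.append(e / e.sum(axis=1, keepdims=True))
    return np.vstack(out)


def save_checkpoint(model, path: str | Path) -> None:
    path = Path(path)
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, config=json.dumps(asdict(model.config)), **arrays)


def load_checkpoint(path: str | Path):
    with np.load(Path(path), allow_pickle=False) as data:
        config = ModelConfig(**json.loads(str(data["config"])))
        arrays = [data[f"param_{i}"] for i in range(len(data.files) - 1)]
    model = build_model(config)
    model.load_state_arrays(arrays)
    return model
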