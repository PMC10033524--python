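"""Training loop: Adam, voxel-wise categorical cross-entropy, Dice monitor.

The model is trained volume-by-volume (batch size 1 by default) with seeded
shuffling. After every epoch the validation loss and validation Dice (plain
argmax, no post-processing) are computed; a checkpoint is kept whenever the
overall validation Dice improves on the running best, and training stops at
``max_epochs`` or after ``patience`` epochs without improvement.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import Adam
from .prep import CLASS_NAMES, LABEL_VALUES, from_onehot
from .unet3d import UNet3D

__all__ = ["TrainConfig", "TrainHistory", "TrainingDivergedError",
           "categorical_cross_entropy", "cross_entropy_grad", "train"]

_EPS = 1e-7  # probability clip before the log


class TrainingDivergedError(RuntimeError):
    """The training loss became non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-4
    max_epochs: int = 200
    patience: int = 15  # epochs without validation-Dice improvement
    batch_size: int = 1
    seed: int = 0
    checkpoint_dir: str | Path | None = None
    target_train_loss: float | None = None  # optional extra stop condition
    restore_best: bool = True  # reload the best-val-Dice state at the end

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1 or self.patience < 1 or self.batch_size < 1:
            raise ValueError("max_epochs, patience and batch_size must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch records plus the best-epoch bookkeeping."""

    records: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_dice: float = -1.0
    checkpoint_epochs: list[int] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def categorical_cross_entropy(prediction: np.ndarray, target: np.ndarray,
                              eps: float = _EPS) -> float:
    """Mean over voxels of the per-voxel class cross-entropy.

    Per voxel the loss is ``-sum_i y_i log p_i`` over the three classes,
    with probabilities clipped at ``eps`` before the log; the reduction over
    voxels (and batch) is the mean.
    """
    prediction = np.asarray(prediction)
    target = np.asarray(target)
    if prediction.shape != target.shape:
        raise ValueError(f"prediction {prediction.shape} vs target {target.shape}")
    p = np.clip(prediction, eps, 1.0)
    per_voxel = -(target * np.log(p)).sum(axis=-1)
    return float(per_voxel.mean())


def cross_entropy_grad(prediction: np.ndarray, target: np.ndarray,
                       eps: float = _EPS) -> np.ndarray:
    """Gradient of :func:`categorical_cross_entropy` w.r.t. the probabilities."""
    n_vox = int(np.prod(prediction.shape[:-1]))
    p = np.clip(prediction, eps, 1.0)
    return (-(target / p) / n_vox).astype(np.float32)


def _dice_binary(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    denom = int(a.sum()) + int(b.sum())
    return 1.0 if denom == 0 else 2.0 * float(inter) / denom


def _validation_metrics(model: UNet3D, val_set) -> dict:
    losses, per_class = [], {name: [] for name in CLASS_NAMES}
    for image, onehot in val_set:
        probs = model.predict(_as_input(image))[0]
        losses.append(categorical_cross_entropy(probs, onehot))
        pred_labels = from_onehot(probs)
        true_labels = from_onehot(onehot)
        for name, value in zip(CLASS_NAMES, LABEL_VALUES):
            per_class[name].append(
                _dice_binary(pred_labels == value, true_labels == value)
            )
    out = {"val_loss": float(np.mean(losses))}
    for name in CLASS_NAMES:
        out[f"val_dice_{name}"] = float(np.mean(per_class[name]))
    out["val_dice_overall"] = float(
        np.mean([out[f"val_dice_{n}"] for n in CLASS_NAMES])
    )
    return out


def _as_input(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 3:
        image = image[..., None]
    return image[None]  # add batch axis


def train(model: UNet3D, train_set, val_set, config: TrainConfig
          ) -> tuple[dict, TrainHistory]:
    """Fit ``model``; returns the best checkpoint state and the history.

    ``train_set``/``val_set`` are sequences of (image, onehot-target) pairs
    at the model's input resolution. The best state (by overall validation
    Dice) is re-loaded into the model before returning.
    """
    if not len(train_set) or not len(val_set):
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    history = TrainHistory()
    best_state = model.state_dict()
    # checkpoints carry the architecture spec alongside the weights
    spec_json = np.array(json.dumps(dataclasses.asdict(model.spec)))
    ckpt_dir = Path(config.checkpoint_dir) if config.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
    since_improved = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_set))
        batch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = np.concatenate([_as_input(train_set[i][0]) for i in idx])
            yb = np.stack([np.asarray(train_set[i][1], dtype=np.float32)
                           for i in idx])
            probs = model.forward(xb, training=True)
            loss = categorical_cross_entropy(probs, yb)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch}"
                )
            opt.zero_grad()
            model.backward(cross_entropy_grad(probs, yb))
            opt.step()
            batch_losses.append(loss)
        record = {"epoch": epoch, "train_loss": float(np.mean(batch_losses))}
        record.update(_validation_metrics(model, val_set))
        improved = record["val_dice_overall"] > history.best_val_dice
        record["improved"] = improved
        history.records.append(record)
        if improved:
            history.best_val_dice = record["val_dice_overall"]
            history.best_epoch = epoch
            history.checkpoint_epochs.append(epoch)
            best_state = model.state_dict()
            if ckpt_dir:
                np.savez(ckpt_dir / f"checkpoint_epoch{epoch:04d}.npz",
                         spec_json=spec_json, **best_state)
            since_improved = 0
        else:
            since_improved += 1
        if since_improved >= config.patience:
            break
        if (config.target_train_loss is not None
                and record["train_loss"] < config.target_train_loss):
            break

    if config.restore_best:
        model.load_state_dict(best_state)
    if ckpt_dir:
        np.savez(ckpt_dir / "best.npz", spec_json=spec_json, **best_state)
        history.to_dataframe().to_csv(ckpt_dir / "history.csv", index=False)
    return best_state, history
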