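"""Training loop: on-the-fly batch generator, Adam, plateau LR schedule.

The regime follows the segmentation study it models: Adam with an initial
learning rate of 1e-4, up to 100 epochs, validation Jaccard and Dice
computed after every epoch, and the learning rate halved when the
validation Jaccard plateaus.  The best-validation-Jaccard parameters are
restored at the end.  Masks are fed to the 2-channel softmax head in a
complementary (one-hot) encoding.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import metrics
from .losses import LossConfig, total_loss
from .models import SegmentationModel
from .nn import Adam

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "BatchStream",
    "make_generator",
    "one_hot_masks",
    "train_model",
    "reduce_lr_on_plateau",
    "evaluate_model",
]


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 16
    lr_factor: float = 0.5
    lr_patience: int = 5
    min_lr: float = 1e-6
    seed: int = 0
    monitor: str = "val_jaccard"

    def __post_init__(self):
        if self.learning_rate < 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate must be >= 0; epochs, batch_size > 0")
        if not (0 < self.lr_factor < 1):
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.lr_patience <= 0 or self.min_lr <= 0:
            raise ValueError("lr_patience and min_lr must be positive")


@dataclass
class TrainingHistory:
    """Per-epoch records; ``lr`` is non-increasing under the plateau rule."""

    loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    jaccard: list[float] = field(default_factory=list)
    val_jaccard: list[float] = field(default_factory=list)
    dice: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(asdict(self))


def one_hot_masks(masks: np.ndarray) -> np.ndarray:
    """Binary masks (N, H, W) -> complementary 2-channel encoding (N, H, W, 2)."""
    masks = np.asarray(masks)
    out = np.empty(masks.shape + (2,), dtype=np.float32)
    out[..., 1] = masks
    out[..., 0] = 1.0 - masks
    return out


class BatchStream:
    """Seeded, shuffling batch stream over an in-memory patch set.

    Yields (images in [0,1] float32 NHWC, one-hot masks) batches covering
    every pair exactly once per epoch; the shuffle order is reproducible
    from the seed and advances deterministically across epochs.
    """

    def __init__(self, images: np.ndarray, masks: np.ndarray,
                 batch_size: int = 16, shuffle: bool = True, seed: int = 0):
        if len(images) == 0:
            raise ValueError("empty patch set")
        if len(images) != len(masks):
            raise ValueError("images and masks differ in length")
        self.x = images.astype(np.float32) / 255.0 if images.dtype == np.uint8 \
            else images.astype(np.float32)
        self.y = one_hot_masks(masks)
        self.masks = np.asarray(masks)
        self.batch_size = batch_size
        self.shuffle = shuffle
        self.rng = np.random.default_rng(seed)

    def __len__(self) -> int:
        return int(np.ceil(len(self.x) / self.batch_size))

    @property
    def n_pairs(self) -> int:
        return len(self.x)

    def batches(self):
        order = np.arange(len(self.x))
        if self.shuffle:
            self.rng.shuffle(order)
        for start in range(0, len(order), self.batch_size):
            idx = order[start:start + self.batch_size]
            yield self.x[idx], self.y[idx]


def make_generator(manifest, batch_size: int = 16, shuffle: bool = True,
                   seed: int = 0, split: str | None = None,
                   base_dir=None) -> BatchStream:
    """Build a batch stream from a manifest DataFrame or CSV path.

    Patch images are loaded once into memory (the synthetic sets are small);
    missing files raise an error naming the path.
    """
    if isinstance(manifest, (str, Path)):
        base_dir = Path(manifest).parent if base_dir is None else Path(base_dir)
        manifest = pd.read_csv(manifest)
    elif base_dir is None:
        base_dir = Path(".")
    else:
        base_dir = Path(base_dir)
    if split is not None:
        manifest = manifest[manifest["split"] == split]
    if len(manifest) == 0:
        raise ValueError("manifest split is empty")
    images, masks = [], []
    for _, row in manifest.iterrows():
        img_path = base_dir / row["image_path"]
        mask_path = base_dir / row["mask_path"]
        for p in (img_path, mask_path):
            if not p.exists():
                raise FileNotFoundError(f"missing patch file: {p}")
        images.append(np.asarray(Image.open(img_path)))
        masks.append(np.asarray(Image.open(mask_path)))
    return BatchStream(np.stack(images), np.stack(masks),
                       batch_size=batch_size, shuffle=shuffle, seed=seed)


def reduce_lr_on_plateau(val_history, current_lr: float,
                         config: TrainingConfig) -> float:
    """Plateau rule on the monitored validation score (higher is better).

    If the best value in the history was achieved more than ``lr_patience``
    epochs ago, the learning rate is multiplied by ``lr_factor`` and floored
    at ``min_lr``; an improvement resets the counter.
    """
    if len(val_history) == 0:
        raise ValueError("history must be non-empty")
    best_epoch = int(np.argmax(val_history))
    epochs_since_best = len(val_history) - 1 - best_epoch
    # reduce when the wait first reaches the patience, then again after each
    # further full patience window (a reduction restarts the counter)
    if epochs_since_best >= config.lr_patience and (
        (epochs_since_best - config.lr_patience) % config.lr_patience == 0
    ):
        return max(current_lr * config.lr_factor, config.min_lr)
    return current_lr


def evaluate_model(model: SegmentationModel, stream: BatchStream,
                   loss_config: LossConfig | None = None) -> dict:
    """Loss and metrics over a full stream (eval mode, no shuffling effect)."""
    loss_config = loss_config or LossConfig()
    probs = []
    for start in range(0, stream.n_pairs, stream.batch_size):
        xb = stream.x[start:start + stream.batch_size]
        out = model.forward(xb, training=False)
        probs.append(out.data)
    probs = np.concatenate(probs, axis=0)
    y_true = stream.masks
    p1 = probs[..., 1]
    pred_labels = (probs[..., 1] > probs[..., 0]).astype(np.uint8)
    loss = total_loss(y_true.astype(np.float32), probs, loss_config)
    overall_iou, per_class = metrics.mean_iou(y_true, pred_labels)
    return {
        "loss": float(loss),
        "jaccard": metrics.jaccard_coef(y_true, p1),
        "dice": metrics.dice_coef(y_true, p1),
        "mean_iou": overall_iou,
        "iou_class0": per_class[0],
        "iou_class1": per_class[1],
    }


def train_model(model: SegmentationModel, train_stream: BatchStream,
                val_stream: BatchStream, config: TrainingConfig | None = None,
                loss_config: LossConfig | None = None,
                verbose: bool = False):
    """Fit a segmentation model; returns (model, TrainingHistory).

    The model is left holding the parameters of the epoch with the highest
    validation Jaccard.  Aborts on a non-finite training loss.
    """
    config = config or TrainingConfig()
    loss_config = loss_config or LossConfig()
    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate)
    history = TrainingHistory()
    best_score = -np.inf
    best_state = [a.copy() for a in model.state_arrays()]
    lr = config.learning_rate

    for epoch in range(config.epochs):
        opt.lr = lr
        epoch_losses, epoch_jacc, epoch_dice = [], [], []
        for xb, yb in train_stream.batches():
            model.zero_grad()
            out = model.forward(xb, training=True)
            loss = total_loss(yb, out, loss_config)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss))
            yb1 = yb[..., 1]
            epoch_jacc.append(metrics.jaccard_coef(yb1, out.data[..., 1]))
            epoch_dice.append(metrics.dice_coef(yb1, out.data[..., 1]))

        val = evaluate_model(model, val_stream, loss_config)
        history.loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val["loss"])
        history.jaccard.append(float(np.mean(epoch_jacc)))
        history.val_jaccard.append(val["jaccard"])
        history.dice.append(float(np.mean(epoch_dice)))
        history.val_dice.append(val["dice"])
        history.lr.append(lr)
        if verbose:
            print(
                f"epoch {epoch + 1}/{config.epochs} "
                f"loss={history.loss[-1]:.4f} val_jaccard={val['jaccard']:.4f} "
                f"val_miou={val['mean_iou']:.4f} lr={lr:.2e}"
            )
        if val["jaccard"] > best_score:
            best_score = val["jaccard"]
            best_state = [a.copy() for a in model.state_arrays()]
        lr = reduce_lr_on_plateau(history.val_jaccard, lr, config)

    model.set_state_arrays(best_state)
    return model, history
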