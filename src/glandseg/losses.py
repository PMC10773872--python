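"""Composite training objective: class-weighted Dice (F-beta) loss + binary focal loss.

The total objective is

    total = dice_loss + focal_multiplier * binary_focal_loss

where the Dice term is built per class from *soft* precision and recall
(probabilities enter the confusion counts directly, no thresholding):

    TP_c = sum(y_c * p_c),  FP_c = sum((1-y_c) * p_c),  FN_c = sum(y_c * (1-p_c))
    F_beta(c) = ((1+beta^2) * precision_c * recall_c + smooth)
                / (beta^2 * precision_c + recall_c + smooth)
    dice_loss = sum_c w_c * (1 - F_beta(c)),  w normalized to sum 1

and the focal term acts on the malignant-class probability p1:

    focal = mean( -y * alpha * (1-p1)^gamma * log(p1)
                  - (1-y) * alpha * p1^gamma * log(1-p1) )

Note the balancing factor alpha multiplies *both* terms here (so gamma=0,
alpha=1 reduces exactly to binary cross-entropy).  All functions accept
plain numpy arrays (returning floats) or autodiff Tensors (returning a
Tensor so gradients can flow to the prediction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, as_tensor

__all__ = [
    "LossConfig",
    "soft_precision_recall",
    "dice_loss",
    "binary_focal_loss",
    "total_loss",
]

_EPS = 1e-7  # probability clip for the focal log terms


@dataclass
class LossConfig:
    """Hyper-parameters of the composite objective.

    beta balances precision vs recall inside the Dice term (beta=1 is the
    symmetric F1 form); alpha and gamma are the focal balancing and focusing
    parameters; smooth guards zero denominators; class_weights re-weight the
    per-class Dice terms (e.g. inverse class frequency).
    """

    beta: float = 1.0
    alpha: float = 0.25
    gamma: float = 2.0
    smooth: float = 1e-5
    class_weights: tuple[float, float] = (1.0, 1.0)
    focal_multiplier: float = 1.0

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.smooth <= 0:
            raise ValueError("smooth must be positive")
        if any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be positive")


def _channels(y_true, y_pred):
    """Split inputs into per-class (y_c, p_c) pairs.

    ``y_true`` is a binary field (…, no channel) or one-hot (…, 2);
    ``y_pred`` is a probability field (…, 2) or the class-1 probability alone.
    Returns Tensors (constants stay out of the graph).
    """
    y_true = as_tensor(y_true)
    y_pred = as_tensor(y_pred)
    yt, yp = y_true.data, y_pred.data
    if yp.ndim == yt.ndim + 1 and yp.shape[-1] == 2 and yp.shape[:-1] == yt.shape:
        p1 = y_pred[..., 1]
        p0 = y_pred[..., 0]
        y1 = Tensor(yt.astype(yp.dtype))
        y0 = Tensor(1.0 - yt.astype(yp.dtype))
    elif yp.shape == yt.shape and yp.ndim >= 2 and yp.shape[-1] == 2:
        # both one-hot / two-channel
        p0, p1 = y_pred[..., 0], y_pred[..., 1]
        y0, y1 = Tensor(yt[..., 0]), Tensor(yt[..., 1])
    else:
        if yp.shape != yt.shape:
            raise ValueError(
                f"shape mismatch: y_true {yt.shape} vs y_pred {yp.shape}"
            )
        p1 = y_pred
        p0 = 1.0 - y_pred
        y1 = Tensor(yt.astype(np.float64 if yp.dtype.kind != "f" else yp.dtype))
        y0 = Tensor(1.0 - y1.data)
    return (y0, p0), (y1, p1)


def soft_precision_recall(y_true, y_pred, c: int, smooth: float = 1e-5):
    """Soft (probability-weighted) precision and recall for class ``c``."""
    pairs = _channels(y_true, y_pred)
    y, p = pairs[c]
    tp = (y * p).sum()
    fp = ((1.0 - y) * p).sum()
    fn = (y * (1.0 - p)).sum()
    precision = (tp + smooth) / (tp + fp + smooth)
    recall = (tp + smooth) / (tp + fn + smooth)
    if isinstance(y_pred, Tensor):
        return precision, recall
    return float(precision), float(recall)


def _dice_loss_t(y_true, y_pred, config: LossConfig) -> Tensor:
    pairs = _channels(y_true, y_pred)
    wsum = sum(config.class_weights)
    weights = [w / wsum for w in config.class_weights]
    b2 = config.beta ** 2
    s = config.smooth
    loss = None
    for c, (y, p) in enumerate(pairs):
        tp = (y * p).sum()
        fp = ((1.0 - y) * p).sum()
        fn = (y * (1.0 - p)).sum()
        precision = (tp + s) / (tp + fp + s)
        recall = (tp + s) / (tp + fn + s)
        fbeta = ((1 + b2) * precision * recall + s) / (b2 * precision + recall + s)
        term = (1.0 - fbeta) * weights[c]
        loss = term if loss is None else loss + term
    return loss


def dice_loss(y_true, y_pred, config: LossConfig | None = None):
    """Class-weighted soft F-beta (Dice) loss; 0 for a perfect hard prediction."""
    config = config or LossConfig()
    out = _dice_loss_t(y_true, y_pred, config)
    return out if isinstance(y_pred, Tensor) else float(out)


def _focal_loss_t(y_true, y_pred, config: LossConfig) -> Tensor:
    pairs = _channels(y_true, y_pred)
    y1, p1 = pairs[1]
    pdata = p1.data if isinstance(p1, Tensor) else np.asarray(p1)
    if pdata.min() < -1e-9 or pdata.max() > 1 + 1e-9:
        raise ValueError("y_pred must contain probabilities in [0, 1]")
    p = p1.clip(_EPS, 1.0 - _EPS)
    a, g = config.alpha, config.gamma
    y = y1
    pos = y * ((1.0 - p) ** g) * p.log() * (-a)
    neg = (1.0 - y) * (p ** g) * (1.0 - p).log() * (-a)
    return (pos + neg).mean()


def binary_focal_loss(y_true, y_pred, config: LossConfig | None = None):
    """Binary focal loss on the malignant-class probability channel (mean
    over pixels, natural logarithm)."""
    config = config or LossConfig()
    out = _focal_loss_t(y_true, y_pred, config)
    return out if isinstance(y_pred, Tensor) else float(out)


def total_loss(y_true, y_pred, config: LossConfig | None = None):
    """dice_loss + focal_multiplier * binary_focal_loss."""
    config = config or LossConfig()
    out = _dice_loss_t(y_true, y_pred, config)
    if config.focal_multiplier != 0.0:
        out = out + config.focal_multiplier * _focal_loss_t(y_true, y_pred, config)
    return out if isinstance(y_pred, Tensor) else float(out)
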