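"""Model ensembling: mean and weighted-mean softmax fusion, grid search,
and paired t-test comparison of methods.

The model ensemble (ME) averages the per-model softmax probability vectors
pixel by pixel; the weighted model ensemble (WME) takes a weighted mean
(weights normalized by their sum, so the argmax is invariant to rescaling
all weights by a positive constant).  The weights are found by exhaustive
grid search over a step lattice, scored by validation mean IoU.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import mean_iou

__all__ = [
    "EnsembleWeights",
    "PairedTestResult",
    "ensemble_probs",
    "weighted_ensemble_probs",
    "predict_class",
    "grid_search_weights",
    "paired_ttest",
]


@dataclass(frozen=True)
class EnsembleWeights:
    """Non-negative per-model weights; at least one must be positive."""

    w: tuple

    def __post_init__(self):
        w = tuple(float(x) for x in self.w)
        if any(x < 0 for x in w):
            raise ValueError("weights must be non-negative")
        if sum(w) <= 0:
            raise ValueError("at least one weight must be positive")
        object.__setattr__(self, "w", w)

    def normalized(self) -> np.ndarray:
        arr = np.asarray(self.w, dtype=np.float64)
        return arr / arr.sum()


@dataclass(frozen=True)
class PairedTestResult:
    t_value: float
    p_value: float
    df: int
    n: int


def _stack_fields(fields) -> np.ndarray:
    fields = [np.asarray(f, dtype=np.float64) for f in fields]
    if not fields:
        raise ValueError("need at least one probability field")
    shape = fields[0].shape
    for f in fields[1:]:
        if f.shape != shape:
            raise ValueError(f"field shape mismatch: {f.shape} vs {shape}")
    return np.stack(fields, axis=0)


def ensemble_probs(fields) -> np.ndarray:
    """Model ensemble: per-pixel arithmetic mean of the softmax vectors."""
    return _stack_fields(fields).mean(axis=0)


def weighted_ensemble_probs(fields, weights) -> np.ndarray:
    """Weighted model ensemble: per-pixel weighted mean of softmax vectors."""
    if not isinstance(weights, EnsembleWeights):
        weights = EnsembleWeights(tuple(weights))
    stacked = _stack_fields(fields)
    if len(weights.w) != stacked.shape[0]:
        raise ValueError(
            f"{len(weights.w)} weights for {stacked.shape[0]} models"
        )
    wn = weights.normalized()
    return np.tensordot(wn, stacked, axes=(0, 0))


def predict_class(field: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over the 2-class probability vector; ties -> class 0."""
    field = np.asarray(field)
    return (field[..., 1] > field[..., 0]).astype(np.uint8)


def _weight_lattice(n_models: int, step: float):
    n_steps = round(1.0 / step)
    if abs(n_steps * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1 evenly")
    values = [round(i * step, 10) for i in range(n_steps + 1)]
    for tup in itertools.product(values, repeat=n_models):
        if any(v > 0 for v in tup):
            yield tup


def grid_search_weights(fields_per_model, y_true, step: float = 0.2):
    """Exhaustive weight search on a validation set.

    ``fields_per_model`` is a list (one entry per model) of stacked
    probability fields (n_patches, H, W, 2); ``y_true`` the matching binary
    masks.  Every tuple in {0, step, ..., 1}^m except all-zero is scored by
    overall mean IoU of the WME argmax prediction; ties resolve to the
    lexicographically smallest tuple.  Returns (EnsembleWeights, score table).
    """
    stacked = _stack_fields(fields_per_model)
    y_true = np.asarray(y_true)
    if y_true.size == 0:
        raise ValueError("empty validation set")
    if y_true.shape != stacked.shape[1:-1]:
        raise ValueError(
            f"mask shape {y_true.shape} does not match fields {stacked.shape[1:-1]}"
        )
    n_models = stacked.shape[0]
    rows = []
    best_tuple, best_score = None, -np.inf
    for tup in _weight_lattice(n_models, step):
        wn = np.asarray(tup, dtype=np.float64)
        wn = wn / wn.sum()
        probs = np.tensordot(wn, stacked, axes=(0, 0))
        pred = (probs[..., 1] > probs[..., 0]).astype(np.uint8)
        overall, per_class = mean_iou(y_true, pred)
        rows.append(
            {**{f"w{i + 1}": tup[i] for i in range(n_models)},
             "mean_iou": overall,
             "iou_class0": per_class[0],
             "iou_class1": per_class[1]}
        )
        if overall > best_score:  # strict: first (lexicographically
            best_score = overall  # smallest) tuple wins ties
            best_tuple = tup
    table = pd.DataFrame(rows)
    return EnsembleWeights(best_tuple), table


def paired_ttest(scores_a, scores_b) -> PairedTestResult:
    """Two-tailed paired t-test on matched score lists.

    t = mean(d) / (sd(d) / sqrt(n)) on the differences d = a - b, with the
    sample standard deviation (n-1 denominator); p from Student's t with
    df = n - 1.  Zero-variance differences make t undefined and raise.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score lists must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two paired observations")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("differences have zero variance; t is undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(t_value=float(t), p_value=float(p), df=n - 1, n=n)
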