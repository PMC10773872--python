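"""Slide-level malignancy probability maps reassembled from patch predictions.

Per-patch malignant-channel probabilities are written back into the patch
grid cells they came from.  Cells whose patch was removed by quality control
(or never predicted) are *missing* — rendered as the bare slide rather than
as probability zero, because a zero would masquerade as a confident benign
call.  A zero-fill mode is available for comparability with pipelines that
conflate the two.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import tifffile
from matplotlib.colors import LinearSegmentedColormap

__all__ = [
    "ScoreMap",
    "assemble_score_map",
    "render_overlay",
    "colorbar_strip",
    "save_score_map",
    "load_score_map",
    "MALIGNANCY_CMAP",
]

# green -> yellow -> orange -> red ramp (cool = low, hot = high probability)
MALIGNANCY_CMAP = LinearSegmentedColormap.from_list(
    "malignancy", ["#0b3d0b", "#2e8b2e", "#b5c924", "#f2a513", "#d91111"]
)


@dataclass
class ScoreMap:
    """Malignancy probability mosaic; NaN marks missing (unpredicted) pixels."""

    values: np.ndarray  # H x W float32, in [0,1] or NaN
    patch_size: int
    filtered_cells: set = field(default_factory=set)
    slide_id: str = "slide"

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def filled(self, fill_value: float = 0.0) -> np.ndarray:
        """Zero-fill (or constant-fill) variant of the map."""
        out = self.values.copy()
        out[np.isnan(out)] = fill_value
        return out


def assemble_score_map(predictions: dict, slide_dims: tuple[int, int],
                       patch_size: int, slide_id: str = "slide",
                       filtered_cells=None) -> ScoreMap:
    """Mosaic per-patch probability fields into a slide-level score map.

    ``predictions`` maps grid index (gy, gx) to an H x W x 2 probability
    field (or an H x W malignant-probability array).  The grid is
    non-overlapping with cell size ``patch_size``.  Cells without a
    prediction stay missing; ``filtered_cells`` records indices dropped by
    quality control for provenance.
    """
    h, w = slide_dims
    values = np.full((h, w), np.nan, dtype=np.float32)
    for (gy, gx), field_arr in predictions.items():
        y, x = gy * patch_size, gx * patch_size
        if y < 0 or x < 0 or y + patch_size > h or x + patch_size > w:
            raise ValueError(
                f"grid cell ({gy}, {gx}) falls outside the {h}x{w} slide"
            )
        arr = np.asarray(field_arr, dtype=np.float32)
        p1 = arr[..., 1] if arr.ndim == 3 else arr
        if p1.shape != (patch_size, patch_size):
            raise ValueError(
                f"cell ({gy}, {gx}): field shape {p1.shape} != "
                f"({patch_size}, {patch_size})"
            )
        values[y:y + patch_size, x:x + patch_size] = p1
    return ScoreMap(
        values=values,
        patch_size=patch_size,
        filtered_cells=set(filtered_cells or ()),
        slide_id=slide_id,
    )


def render_overlay(slide_rgb: np.ndarray, score_map: ScoreMap,
                   colormap=MALIGNANCY_CMAP, alpha: float = 0.5,
                   missing_as_zero: bool = False) -> np.ndarray:
    """Alpha-blend the probability map over the slide image.

    Missing cells show the original slide (default) or are treated as
    probability 0 when ``missing_as_zero`` is set.  Returns uint8 RGB.
    """
    slide_rgb = np.asarray(slide_rgb)
    values = score_map.filled(0.0) if missing_as_zero else score_map.values
    if slide_rgb.shape[:2] != values.shape:
        raise ValueError(
            f"slide {slide_rgb.shape[:2]} and score map {values.shape} "
            "dimensions differ"
        )
    if isinstance(colormap, str):
        colormap = matplotlib.colormaps[colormap]
    valid = ~np.isnan(values)
    out = slide_rgb.astype(np.float64).copy()
    if valid.any():
        colors = colormap(np.nan_to_num(values))[..., :3] * 255.0
        out[valid] = (1 - alpha) * out[valid] + alpha * colors[valid]
    return np.clip(out, 0, 255).astype(np.uint8)


def colorbar_strip(colormap=MALIGNANCY_CMAP, height: int = 16,
                   width: int = 256) -> np.ndarray:
    """A horizontal color-bar image (low probability left, high right)."""
    if isinstance(colormap, str):
        colormap = matplotlib.colormaps[colormap]
    ramp = np.linspace(0, 1, width)
    strip = colormap(np.tile(ramp, (height, 1)))[..., :3] * 255.0
    return strip.astype(np.uint8)


def save_score_map(score_map: ScoreMap, path) -> None:
    """Persist as 32-bit float TIFF plus a JSON sidecar with provenance."""
    path = Path(path)
    tifffile.imwrite(path, score_map.values.astype(np.float32))
    sidecar = {
        "slide_id": score_map.slide_id,
        "patch_size": score_map.patch_size,
        "filtered_cells": sorted([list(c) for c in score_map.filtered_cells]),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_score_map(path) -> ScoreMap:
    path = Path(path)
    values = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ScoreMap(
        values=values,
        patch_size=int(meta["patch_size"]),
        filtered_cells={tuple(c) for c in meta["filtered_cells"]},
        slide_id=meta["slide_id"],
    )
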