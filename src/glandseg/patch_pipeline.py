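"""Slide → patch preprocessing: rasterization, binarization, quality filtering.

The annotation taxonomy uses 11 tissue labels; the binary task maps
Gleason pattern 3 and 4 glands to the malignant class (1) and every other
label — background, foreground, benign glands, GP5, lymphoid, not-evaluated,
not-sure, PIN, blood — to 0.  Patch quality control keeps a patch only if

* its tissue ratio (fraction of non-white pixels in the RGB image) is at
  least ``min_tissue_ratio`` (default 0.2), and
* its label raster contains at least one pixel annotated with a tissue
  class other than Bg/Fg (so patches of pure background/foreground mixtures
  are dropped).

Coordinates are 0-based (row, col) with half-open pixel ranges; grid index
(gy, gx) covers pixels [gy*stride, gy*stride+patch) x [gx*stride, ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath

__all__ = [
    "LABEL_CODES",
    "LABEL_NAMES",
    "MALIGNANT_LABELS",
    "PatchPair",
    "ClassWeights",
    "rasterize_annotations",
    "binarize_mask",
    "tissue_ratio",
    "extract_patches",
    "filter_patches",
    "compute_class_weights",
    "read_geojson_annotations",
    "write_geojson_annotations",
]

# Annotation taxonomy: code <-> name bijection.
LABEL_NAMES = ("Bg", "Fg", "N", "GP3", "GP4", "GP5", "L", "NE", "NS", "PIN", "Blood")
LABEL_CODES = {name: code for code, name in enumerate(LABEL_NAMES)}
MALIGNANT_LABELS = frozenset({"GP3", "GP4"})
_NONTISSUE_CODES = frozenset({LABEL_CODES["Bg"], LABEL_CODES["Fg"]})


@dataclass
class PatchPair:
    """An RGB patch, its label (or binary) mask, and its grid position."""

    image: np.ndarray  # H x W x 3, uint8
    mask: np.ndarray   # H x W integer labels (taxonomy codes or {0,1})
    slide_id: str = "slide"
    grid_x: int = 0
    grid_y: int = 0
    magnification_tag: str = "20x"

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} "
                "spatial shapes differ"
            )


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights (benign w0, malignant w1)."""

    w0: float
    w1: float

    def __post_init__(self):
        if self.w0 <= 0 or self.w1 <= 0:
            raise ValueError("class weights must be positive")

    def as_tuple(self) -> tuple[float, float]:
        return (self.w0, self.w1)


def rasterize_annotations(polygons, canvas_size) -> np.ndarray:
    """Paint labeled polygons onto a label raster.

    ``polygons`` is a sequence of (label_name, vertices) with vertices as
    (x, y) pairs in pixel units.  Pixels whose centers fall inside a polygon
    receive its code; uncovered pixels stay Bg; later polygons overwrite
    earlier ones (document order wins).
    """
    h, w = canvas_size
    raster = np.full((h, w), LABEL_CODES["Bg"], dtype=np.uint8)
    for label, verts in polygons:
        if label not in LABEL_CODES:
            raise ValueError(
                f"unknown label {label!r}; valid labels: {', '.join(LABEL_NAMES)}"
            )
        verts = np.asarray(verts, dtype=float)
        path = MplPath(verts)
        x0, y0 = np.floor(verts.min(axis=0)).astype(int)
        x1, y1 = np.ceil(verts.max(axis=0)).astype(int)
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w), min(y1, h)
        if x1 <= x0 or y1 <= y0:
            continue
        xs, ys = np.meshgrid(
            np.arange(x0, x1) + 0.5, np.arange(y0, y1) + 0.5
        )
        inside = path.contains_points(
            np.column_stack([xs.ravel(), ys.ravel()])
        ).reshape(y1 - y0, x1 - x0)
        raster[y0:y1, x0:x1][inside] = LABEL_CODES[label]
    return raster


def binarize_mask(label_raster: np.ndarray) -> np.ndarray:
    """Map taxonomy codes to {0 benign, 1 malignant}; malignant = GP3 | GP4."""
    raster = np.asarray(label_raster)
    if raster.size and (raster.min() < 0 or raster.max() >= len(LABEL_NAMES)):
        raise ValueError(
            f"label codes must lie in [0, {len(LABEL_NAMES) - 1}]"
        )
    malignant = np.isin(
        raster, [LABEL_CODES[name] for name in sorted(MALIGNANT_LABELS)]
    )
    return malignant.astype(np.uint8)


def tissue_ratio(image: np.ndarray, whiteness_threshold: int = 220) -> float:
    """Fraction of non-background pixels in an RGB patch.

    A pixel counts as background (glass/white space) when its *minimum*
    channel value exceeds ``whiteness_threshold`` (8-bit scale).
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    background = image.min(axis=-1) > whiteness_threshold
    return float(1.0 - background.mean())


def extract_patches(slide: np.ndarray, labels: np.ndarray, patch_size: int,
                    stride: int | None = None, slide_id: str = "slide"
                    ) -> list[PatchPair]:
    """Cut a slide and its label raster into a regular patch grid.

    Partial border patches are dropped; with ``stride == patch_size`` the
    grid is non-overlapping and exactly invertible by the score-map
    assembly.  Grid indices are (row, col) in stride units.
    """
    slide = np.asarray(slide)
    labels = np.asarray(labels)
    if stride is None:
        stride = patch_size
    if stride <= 0:
        raise ValueError("stride must be positive")
    h, w = labels.shape
    if patch_size > h or patch_size > w:
        raise ValueError("patch_size exceeds slide dimensions")
    pairs = []
    for gy, y in enumerate(range(0, h - patch_size + 1, stride)):
        for gx, x in enumerate(range(0, w - patch_size + 1, stride)):
            pairs.append(
                PatchPair(
                    image=slide[y:y + patch_size, x:x + patch_size],
                    mask=labels[y:y + patch_size, x:x + patch_size],
                    slide_id=slide_id,
                    grid_x=gx,
                    grid_y=gy,
                )
            )
    return pairs


def _has_tissue_class(label_mask: np.ndarray) -> bool:
    codes = np.unique(label_mask)
    return bool(np.any(~np.isin(codes, list(_NONTISSUE_CODES))))


def filter_patches(pairs, min_tissue_ratio: float = 0.2,
                   require_tissue_class: bool = True,
                   ratio_basis: str = "image",
                   whiteness_threshold: int = 220) -> list[PatchPair]:
    """Quality control: keep pairs passing the tissue-ratio and label tests.

    ``ratio_basis`` selects how the 20% ratio is measured: ``"image"``
    (non-white pixels of the RGB patch, the default) or ``"mask"``
    (non-Bg pixels of the label raster).
    """
    kept = []
    for pair in pairs:
        if ratio_basis == "image":
            ratio = tissue_ratio(pair.image, whiteness_threshold)
        elif ratio_basis == "mask":
            ratio = float(np.mean(pair.mask != LABEL_CODES["Bg"]))
        else:
            raise ValueError("ratio_basis must be 'image' or 'mask'")
        if ratio < min_tissue_ratio:
            continue
        if require_tissue_class and not _has_tissue_class(pair.mask):
            continue
        kept.append(pair)
    return kept


def compute_class_weights(masks, basis: str = "pixel") -> ClassWeights:
    """Inverse-frequency class weights w_c = N_total / (2 * N_c).

    ``masks`` is an iterable of binary masks (training split).  With
    ``basis="patch"`` each patch counts once per class it contains instead
    of per pixel.
    """
    n0 = n1 = 0
    for mask in masks:
        mask = np.asarray(mask)
        if basis == "pixel":
            ones = int(mask.sum())
            n1 += ones
            n0 += mask.size - ones
        elif basis == "patch":
            n1 += int(mask.any())
            n0 += int((mask == 0).any())
        else:
            raise ValueError("basis must be 'pixel' or 'patch'")
    total = n0 + n1
    if n0 == 0 or n1 == 0:
        raise ValueError(
            "one class is absent from the training masks; pass explicit "
            "class weights instead of computing them"
        )
    return ClassWeights(w0=total / (2.0 * n0), w1=total / (2.0 * n1))


# ---------------------------------------------------------------------------
# GeoJSON annotation I/O
# ---------------------------------------------------------------------------

def read_geojson_annotations(path) -> list[tuple[str, np.ndarray]]:
    """Read (label, vertices) polygons from a GeoJSON FeatureCollection.

    Each feature must be a Polygon with a ``label`` property naming one of
    the taxonomy labels; only exterior rings are used.
    """
    with open(path) as fh:
        doc = json.load(fh)
    polygons = []
    for feat in doc.get("features", []):
        label = feat.get("properties", {}).get("label")
        if label not in LABEL_CODES:
            raise ValueError(
                f"unknown label {label!r} in {path}; valid: {', '.join(LABEL_NAMES)}"
            )
        geom = feat["geometry"]
        if geom["type"] != "Polygon":
            raise ValueError(f"unsupported geometry type {geom['type']!r}")
        exterior = np.asarray(geom["coordinates"][0], dtype=float)
        polygons.append((label, exterior))
    return polygons


def write_geojson_annotations(polygons, path) -> None:
    features = []
    for label, verts in polygons:
        verts = np.asarray(verts, dtype=float)
        ring = verts.tolist()
        if ring and ring[0] != ring[-1]:
            ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "properties": {"label": label},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
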