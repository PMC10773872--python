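"""Seeded synthetic H&E-like patches and toy slides with exact ground truth.

The generator paints a stylized hematoxylin–eosin look: pink stroma, white
gland lumina, purple epithelial rings with dark nuclear speckle.  Three gland
morphologies mirror the histologic archetypes at toy scale:

* benign — a few large rings with wide open lumina and pale epithelium;
* GP3-like — many small, discrete, well-formed rings;
* GP4-like — fused masses built from overlapping ellipses with scattered
  slit-like lumina.

Malignant epithelium is rendered darker and with denser nuclear speckle than
benign epithelium (hyperchromasia), so the toy task carries both a color and
a shape cue.  Realism is a non-goal: these images exist so that every
downstream stage — filtering, training, ensembling, map reconstruction — is
testable without any external dataset.  Fixing the seed makes every product
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .patch_pipeline import (
    LABEL_CODES,
    PatchPair,
    rasterize_annotations,
)

__all__ = [
    "GlandStyle",
    "CoreSpec",
    "SlideLayout",
    "generate_patch_pair",
    "generate_toy_slide",
    "generate_dataset",
    "load_dataset",
]

# stylized H&E palette (uint8 RGB)
STROMA = np.array([233, 178, 199], dtype=np.float32)
LUMEN = np.array([246, 243, 246], dtype=np.float32)
BENIGN_EPI = np.array([177, 126, 190], dtype=np.float32)
MALIG_EPI = np.array([122, 76, 150], dtype=np.float32)
NUCLEUS = np.array([72, 38, 105], dtype=np.float32)

DEFAULT_NOISE_SIGMA = 8.0  # additive Gaussian noise on 8-bit channels


@dataclass
class GlandStyle:
    """Morphology parameters for one gland population.

    ``crowding`` is the target fraction of the patch area covered by glands
    (the malignant pixel fraction for the malignant kinds).
    """

    kind: str = "benign"  # benign | gp3_like | gp4_like
    lumen_radius_px: float = 10.0
    ring_thickness_px: float = 4.0
    crowding: float = 0.3

    def __post_init__(self):
        if self.kind not in ("benign", "gp3_like", "gp4_like"):
            raise ValueError(f"unknown gland kind {self.kind!r}")
        if self.lumen_radius_px <= 0 or self.ring_thickness_px <= 0:
            raise ValueError("radii must be positive")
        if not (0.0 <= self.crowding <= 1.0):
            raise ValueError("crowding must lie in [0, 1]")

    @classmethod
    def preset(cls, kind: str, crowding: float | None = None) -> "GlandStyle":
        presets = {
            "benign": dict(lumen_radius_px=9.0, ring_thickness_px=4.0, crowding=0.30),
            "gp3_like": dict(lumen_radius_px=2.0, ring_thickness_px=3.0, crowding=0.25),
            "gp4_like": dict(lumen_radius_px=1.5, ring_thickness_px=7.0, crowding=0.30),
        }
        kwargs = dict(presets[kind])
        if crowding is not None:
            kwargs["crowding"] = crowding
        return cls(kind=kind, **kwargs)

    @property
    def malignant(self) -> bool:
        return self.kind in ("gp3_like", "gp4_like")


@dataclass
class CoreSpec:
    """One elliptical tissue core on a toy slide."""

    center: tuple[float, float]  # (x, y) pixels
    axes: tuple[float, float]    # semi-axes (a, b)
    rotation: float = 0.0        # radians
    label: str = "N"             # taxonomy label for the whole core


@dataclass
class SlideLayout:
    """Geometry of a toy slide: canvas, cores, background, seed."""

    width_px: int = 512
    height_px: int = 512
    cores: list[CoreSpec] = field(default_factory=list)
    background_color: tuple[int, int, int] = (245, 243, 245)
    seed: int = 0

    def __post_init__(self):
        for i, core in enumerate(self.cores):
            cx, cy = core.center
            r = max(core.axes)
            if not (0 <= cx - r and cx + r <= self.width_px
                    and 0 <= cy - r and cy + r <= self.height_px):
                raise ValueError(f"core {i} ({core.label}) extends outside the canvas")
            if core.label not in LABEL_CODES:
                raise ValueError(f"core {i} has unknown label {core.label!r}")


# ---------------------------------------------------------------------------
# gland painting primitives
# ---------------------------------------------------------------------------

def _disk(shape, cy, cx, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


def _draw_gland(rgb, gland_mask_out, style: GlandStyle, cy: float, cx: float,
                rng: np.random.Generator, region=None):
    """Paint one gland at (cy, cx); returns the painted footprint mask."""
    h, w = gland_mask_out.shape
    r_lumen = style.lumen_radius_px
    r_out = r_lumen + style.ring_thickness_px
    epi_color = MALIG_EPI if style.malignant else BENIGN_EPI

    if style.kind == "gp4_like":
        # fused mass: union of overlapping ellipse-ish disks
        footprint = np.zeros((h, w), dtype=bool)
        n_blobs = int(rng.integers(3, 6))
        for _ in range(n_blobs):
            dy, dx = rng.normal(scale=r_out * 0.7, size=2)
            rr = r_out * rng.uniform(0.7, 1.1)
            footprint |= _disk((h, w), cy + dy, cx + dx, rr)
        lumen = np.zeros((h, w), dtype=bool)
        for _ in range(n_blobs):
            dy, dx = rng.normal(scale=r_out * 0.6, size=2)
            lumen |= _disk((h, w), cy + dy, cx + dx, style.lumen_radius_px)
        lumen &= footprint
    else:
        footprint = _disk((h, w), cy, cx, r_out)
        lumen = _disk((h, w), cy, cx, r_lumen)

    if region is not None:
        footprint &= region
        lumen &= region
    ring = footprint & ~lumen
    rgb[ring] = epi_color
    rgb[lumen] = LUMEN
    # nuclear speckle along the epithelium
    density = 0.35 if style.malignant else 0.15
    speckle = ring & (rng.random((h, w)) < density)
    rgb[speckle] = NUCLEUS
    gland_mask_out |= footprint
    return footprint


def _paint_glands(rgb, style: GlandStyle, rng: np.random.Generator,
                  region=None, target_fraction: float | None = None,
                  max_attempts: int = 400) -> np.ndarray:
    """Place glands until their union covers the target area fraction."""
    h, w = rgb.shape[:2]
    covered = np.zeros((h, w), dtype=bool)
    target = style.crowding if target_fraction is None else target_fraction
    if target <= 0:
        return covered
    area = region.sum() if region is not None else h * w
    if area == 0:
        return covered
    if region is not None:
        ys, xs = np.nonzero(region)
    for _ in range(max_attempts):
        if covered.sum() / area >= target:
            break
        if region is not None:
            k = int(rng.integers(len(ys)))
            cy, cx = float(ys[k]), float(xs[k])
        else:
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, w)
        _draw_gland(rgb, covered, style, cy, cx, rng, region=region)
    return covered


def generate_patch_pair(style: GlandStyle, size: int, seed: int,
                        noise_sigma: float = DEFAULT_NOISE_SIGMA,
                        malignant_fraction: float | None = None) -> PatchPair:
    """Generate one synthetic RGB patch with a pixel-accurate binary mask.

    The mask is 1 exactly on gland footprints of the malignant styles
    (gp3_like / gp4_like); benign patches have an all-zero mask.  The same
    (style, size, seed) always yields byte-identical output.
    """
    if size < 32:
        raise ValueError("patch size must be at least 32 pixels")
    rng = np.random.default_rng(seed)
    rgb = np.empty((size, size, 3), dtype=np.float32)
    rgb[:] = STROMA
    covered = _paint_glands(rgb, style, rng, target_fraction=malignant_fraction)
    if noise_sigma > 0:
        rgb += rng.normal(scale=noise_sigma, size=rgb.shape)
    image = np.clip(rgb, 0, 255).astype(np.uint8)
    mask = covered.astype(np.uint8) if style.malignant else np.zeros(
        (size, size), dtype=np.uint8
    )
    return PatchPair(image=image, mask=mask, slide_id=f"synthetic-{style.kind}")


# ---------------------------------------------------------------------------
# toy slides
# ---------------------------------------------------------------------------

_CORE_STYLE = {
    "N": "benign",
    "GP3": "gp3_like",
    "GP4": "gp4_like",
}


def _ellipse_polygon(core: CoreSpec, n_vertices: int = 72) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    a, b = core.axes
    x = a * np.cos(t)
    y = b * np.sin(t)
    c, s = np.cos(core.rotation), np.sin(core.rotation)
    xr = core.center[0] + c * x - s * y
    yr = core.center[1] + s * x + c * y
    return np.column_stack([xr, yr])


def generate_toy_slide(layout: SlideLayout):
    """Render a toy slide: RGB raster, label raster, and annotation polygons.

    The label raster is produced by rasterizing the returned polygons, so
    ``rasterize_annotations(polygons) == label_raster`` holds exactly.
    Overlapping cores with different labels raise an error naming the
    collision.
    """
    h, w = layout.height_px, layout.width_px
    polygons = [(core.label, _ellipse_polygon(core)) for core in layout.cores]

    # conflict detection: rasterize each core alone
    core_masks = []
    for (label, verts) in polygons:
        single = rasterize_annotations([("GP3", verts)], (h, w)) == LABEL_CODES["GP3"]
        core_masks.append(single)
    for i in range(len(core_masks)):
        for j in range(i + 1, len(core_masks)):
            if layout.cores[i].label != layout.cores[j].label and np.any(
                core_masks[i] & core_masks[j]
            ):
                raise ValueError(
                    f"cores {i} ({layout.cores[i].label}) and {j} "
                    f"({layout.cores[j].label}) overlap with conflicting labels"
                )

    label_raster = rasterize_annotations(polygons, (h, w))

    rng = np.random.default_rng(layout.seed)
    rgb = np.empty((h, w, 3), dtype=np.float32)
    rgb[:] = np.asarray(layout.background_color, dtype=np.float32)
    for core, region in zip(layout.cores, core_masks):
        rgb[region] = STROMA
        style_kind = _CORE_STYLE.get(core.label)
        if style_kind is not None:
            style = GlandStyle.preset(style_kind)
            _paint_glands(rgb, style, rng, region=region)
        elif core.label == "Blood":
            rgb[region] = np.array([190, 60, 70], dtype=np.float32)
    rgb += rng.normal(scale=DEFAULT_NOISE_SIGMA * 0.5, size=rgb.shape)
    slide = np.clip(rgb, 0, 255).astype(np.uint8)
    return slide, label_raster, polygons


# ---------------------------------------------------------------------------
# datasets on disk
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["patch_id", "slide_id", "x", "y", "split",
                    "image_path", "mask_path"]


def generate_dataset(n_train: int, n_val: int, n_test: int, seed: int,
                     out_dir, patch_size: int = 64,
                     kinds=("benign", "gp3_like", "gp4_like")) -> pd.DataFrame:
    """Write a seeded patch dataset and its manifest CSV to ``out_dir``.

    Patches cycle uniformly at random over the gland kinds; malignant kinds
    draw their target coverage from U(0.15, 0.45).  Returns the manifest
    (also written to ``out_dir/manifest.csv``; image/mask paths are relative
    to ``out_dir``).
    """
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("split sizes must be non-negative")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "images").mkdir(exist_ok=True)
    (out_dir / "masks").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0
    for split, n in (("train", n_train), ("val", n_val), ("test", n_test)):
        for i in range(n):
            kind = kinds[int(rng.integers(len(kinds)))]
            crowding = float(rng.uniform(0.15, 0.45))
            style = GlandStyle.preset(kind, crowding=crowding)
            pair_seed = int(rng.integers(2 ** 31))
            pair = generate_patch_pair(style, patch_size, pair_seed)
            patch_id = f"{split}_{i:05d}"
            image_rel = f"images/{patch_id}.png"
            mask_rel = f"masks/{patch_id}.png"
            Image.fromarray(pair.image).save(out_dir / image_rel)
            Image.fromarray(pair.mask).save(out_dir / mask_rel)
            rows.append(
                dict(patch_id=patch_id, slide_id=pair.slide_id, x=i, y=0,
                     split=split, image_path=image_rel, mask_path=mask_rel)
            )
            counter += 1
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_dataset(manifest_path, split: str | None = None):
    """Load a generated dataset back into arrays.

    Returns (images, masks, manifest) with images N x H x W x 3 uint8 and
    masks N x H x W uint8 in {0, 1}.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    if split is not None:
        manifest = manifest[manifest["split"] == split].reset_index(drop=True)
    images, masks = [], []
    for _, row in manifest.iterrows():
        img_path = base / row["image_path"]
        if not img_path.exists():
            raise FileNotFoundError(f"missing patch image: {img_path}")
        images.append(np.asarray(Image.open(img_path)))
        masks.append(np.asarray(Image.open(base / row["mask_path"])))
    if images:
        return np.stack(images), np.stack(masks), manifest
    return (np.zeros((0, 0, 0, 3), dtype=np.uint8),
            np.zeros((0, 0, 0), dtype=np.uint8), manifest)
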