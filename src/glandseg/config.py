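"""Pipeline configuration and end-to-end orchestration.

``run_pipeline`` chains the stages: simulate synthetic data → preprocess
(class weights) → train the three families → ensemble grid search and
paired t-tests → slide-level probability map, writing every artifact under
``cfg.runs_dir``.  Each artifact embeds the hash of the configuration that
produced it.  The default configuration is a deliberately tiny synthetic
study that completes on a laptop CPU.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import synthetic_data, patch_pipeline, training, ensemble as ens, slide_map
from .losses import LossConfig
from .metrics import mean_iou
from .models import ModelSpec, build_model, SegmentationModel
from .training import TrainingConfig, BatchStream

__all__ = [
    "PipelineConfig",
    "load_config",
    "config_hash",
    "run_pipeline",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class PipelineConfig:
    # paths
    data_dir: str = "data"
    runs_dir: str = "runs"
    maps_dir: str = "maps"
    # synthetic data
    n_train: int = 32
    n_val: int = 8
    n_test: int = 8
    patch_size: int = 64
    # preprocessing
    stride: int | None = None
    min_tissue_ratio: float = 0.2
    # models
    families: tuple = ("unet", "aunet", "arunet")
    depth: int = 3
    base_filters: int = 8
    # loss
    beta: float = 1.0
    alpha: float = 0.25
    gamma: float = 2.0
    smooth: float = 1e-5
    class_weights: str | tuple = "auto"
    focal_multiplier: float = 1.0
    # training
    learning_rate: float = 1e-3
    epochs: int = 3
    batch_size: int = 16
    lr_factor: float = 0.5
    lr_patience: int = 5
    min_lr: float = 1e-6
    # ensemble
    grid_step: float = 0.2
    k_repeats: int = 3
    # seeds
    seed: int = 0

    def model_spec(self, family: str) -> ModelSpec:
        return ModelSpec(
            family=family, depth=self.depth, base_filters=self.base_filters,
            input_size=self.patch_size, seed=self.seed,
        )

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(
            learning_rate=self.learning_rate, epochs=self.epochs,
            batch_size=self.batch_size, lr_factor=self.lr_factor,
            lr_patience=self.lr_patience, min_lr=self.min_lr, seed=self.seed,
        )

    def loss_config(self, class_weights=None) -> LossConfig:
        if class_weights is None:
            cw = (1.0, 1.0) if self.class_weights == "auto" else tuple(self.class_weights)
        else:
            cw = tuple(class_weights)
        return LossConfig(
            beta=self.beta, alpha=self.alpha, gamma=self.gamma,
            smooth=self.smooth, class_weights=cw,
            focal_multiplier=self.focal_multiplier,
        )


def load_config(path) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(
            f"unknown config keys: {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    if "families" in raw:
        raw["families"] = tuple(raw["families"])
    return PipelineConfig(**raw)


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def save_checkpoint(model: SegmentationModel, path,
                    extra: dict | None = None) -> None:
    """Parameters as .npz plus a JSON sidecar with the model spec."""
    path = Path(path)
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, **arrays)
    sidecar = {"model_spec": asdict(model.spec)}
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> SegmentationModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    model = build_model(ModelSpec(**meta["model_spec"]))
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        arrays = [data[f"param_{i}"] for i in range(len(data.files))]
    model.set_state_arrays(arrays)
    return model


def _predict_fields(model: SegmentationModel, stream: BatchStream) -> np.ndarray:
    out = []
    for start in range(0, stream.n_pairs, stream.batch_size):
        xb = stream.x[start:start + stream.batch_size]
        out.append(model.forward(xb, training=False).data)
    return np.concatenate(out, axis=0)


def paired_method_scores(method_fields: dict, y_true: np.ndarray,
                         k: int = 3, seed: int = 0,
                         subsample: float = 0.5) -> pd.DataFrame:
    """Per-repeat overall mean IoU for each prediction method.

    Each of the ``k`` seeded repeats scores every method on the same random
    subsample of validation patches, giving matched observations for the
    paired t-test.  Returns a DataFrame (rows = repeats, columns = methods).
    """
    n = len(y_true)
    rows = []
    for r in range(k):
        rng = np.random.default_rng(seed + r)
        m = max(2, int(round(subsample * n)))
        idx = rng.choice(n, size=m, replace=False)
        row = {}
        for name, probs in method_fields.items():
            pred = ens.predict_class(probs[idx])
            row[name], _ = mean_iou(y_true[idx], pred)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig, dry_run: bool = False,
                 verbose: bool = True) -> dict:
    """Execute the full synthetic study; returns a dict of key results.

    Stages: simulate → preprocess → train x families → ensemble (grid
    search + t-tests) → toy-slide probability map.  All artifacts land under
    ``cfg.runs_dir`` / ``cfg.maps_dir`` and embed the config hash.
    """
    stages = ["simulate", "preprocess", "train", "ensemble", "slide_map"]
    if dry_run:
        for s in stages:
            print(f"stage: {s}")
        return {"stages": stages}

    chash = config_hash(cfg)
    t0 = time.time()
    data_dir, runs_dir, maps_dir = (
        Path(cfg.data_dir), Path(cfg.runs_dir), Path(cfg.maps_dir)
    )
    runs_dir.mkdir(parents=True, exist_ok=True)
    maps_dir.mkdir(parents=True, exist_ok=True)

    def log(msg):
        if verbose:
            print(f"[{time.time() - t0:7.1f}s] {msg}")

    # -- simulate ----------------------------------------------------------
    log("simulate: generating synthetic dataset")
    synthetic_data.generate_dataset(
        cfg.n_train, cfg.n_val, cfg.n_test, cfg.seed, data_dir,
        patch_size=cfg.patch_size,
    )
    manifest_path = data_dir / "manifest.csv"

    # -- preprocess --------------------------------------------------------
    log("preprocess: class weights from training masks")
    streams = {
        split: training.make_generator(
            manifest_path, batch_size=cfg.batch_size,
            shuffle=(split == "train"), seed=cfg.seed, split=split,
        )
        for split in ("train", "val", "test")
    }
    if cfg.class_weights == "auto":
        cw = patch_pipeline.compute_class_weights(streams["train"].masks)
        class_weights = cw.as_tuple()
    else:
        class_weights = tuple(cfg.class_weights)
    loss_cfg = cfg.loss_config(class_weights)
    log(f"preprocess: class weights = ({class_weights[0]:.3f}, {class_weights[1]:.3f})")

    # -- train -------------------------------------------------------------
    models, metrics_rows = {}, []
    for family in cfg.families:
        log(f"train: {family}")
        model = build_model(cfg.model_spec(family))
        # fresh seeded stream per family so every model sees the same order
        tr = BatchStream(
            streams["train"].x, streams["train"].masks,
            batch_size=cfg.batch_size, shuffle=True, seed=cfg.seed,
        )
        model, history = training.train_model(
            model, tr, streams["val"], cfg.training_config(), loss_cfg,
        )
        models[family] = model
        hist = history.to_frame()
        hist["config_hash"] = chash
        hist.to_csv(runs_dir / f"{family}_history.csv", index=False)
        save_checkpoint(
            model, runs_dir / f"{family}.npz",
            extra={"config_hash": chash, "training": asdict(cfg.training_config())},
        )
        for split in ("val", "test"):
            scores = training.evaluate_model(model, streams[split], loss_cfg)
            metrics_rows.append(
                {"set": split, "model": family,
                 "jaccard": scores["jaccard"], "dice": scores["dice"],
                 "mean_iou": scores["mean_iou"],
                 "iou_class0": scores["iou_class0"],
                 "iou_class1": scores["iou_class1"],
                 "config_hash": chash}
            )
            log(f"  {family} {split}: mean IoU {scores['mean_iou']:.4f}")
    metrics_df = pd.DataFrame(metrics_rows)
    metrics_df.to_csv(runs_dir / "metrics.csv", index=False)

    # -- ensemble ----------------------------------------------------------
    log("ensemble: grid search on validation predictions")
    val_fields = {f: _predict_fields(m, streams["val"]) for f, m in models.items()}
    y_val = streams["val"].masks
    fields_list = [val_fields[f] for f in cfg.families]
    best_w, table = ens.grid_search_weights(fields_list, y_val, step=cfg.grid_step)
    table["config_hash"] = chash
    table.to_csv(runs_dir / "grid_search.csv", index=False)
    log(f"ensemble: best weights {best_w.w}")

    method_fields = dict(val_fields)
    method_fields["ME"] = ens.ensemble_probs(fields_list)
    method_fields["WME"] = ens.weighted_ensemble_probs(fields_list, best_w)
    scores_df = paired_method_scores(
        method_fields, y_val, k=cfg.k_repeats, seed=cfg.seed,
    )
    ttest_rows = []
    names = list(method_fields)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = scores_df[names[i]].values, scores_df[names[j]].values
            try:
                res = ens.paired_ttest(a, b)
                ttest_rows.append(
                    {"pair": f"{names[i]} vs {names[j]}",
                     "t_value": res.t_value, "p_value": res.p_value,
                     "df": res.df, "config_hash": chash}
                )
            except ValueError:
                ttest_rows.append(
                    {"pair": f"{names[i]} vs {names[j]}",
                     "t_value": np.nan, "p_value": np.nan,
                     "df": cfg.k_repeats - 1, "config_hash": chash}
                )
    ttest_df = pd.DataFrame(ttest_rows)
    ttest_df.to_csv(runs_dir / "ttest.csv", index=False)

    # -- slide map ---------------------------------------------------------
    log("slide_map: toy slide prediction and reconstruction")
    side = cfg.patch_size * 4
    r = cfg.patch_size * 0.7
    layout = synthetic_data.SlideLayout(
        width_px=side, height_px=side,
        cores=[
            synthetic_data.CoreSpec((side * 0.28, side * 0.3), (r, r * 0.8),
                                    0.4, "N"),
            synthetic_data.CoreSpec((side * 0.72, side * 0.32), (r, r * 0.75),
                                    -0.3, "GP3"),
            synthetic_data.CoreSpec((side * 0.5, side * 0.74), (r * 1.1, r * 0.7),
                                    0.2, "GP4"),
        ],
        seed=cfg.seed,
    )
    slide, labels, polygons = synthetic_data.generate_toy_slide(layout)
    pairs = patch_pipeline.extract_patches(slide, labels, cfg.patch_size,
                                           slide_id="toy-slide")
    kept = patch_pipeline.filter_patches(pairs, cfg.min_tissue_ratio)
    kept_cells = {(p.grid_y, p.grid_x) for p in kept}
    filtered_cells = {(p.grid_y, p.grid_x) for p in pairs} - kept_cells
    predictions = {}
    for p in kept:
        x = p.image.astype(np.float32)[None] / 255.0
        fields = [models[f].forward(x, training=False).data[0]
                  for f in cfg.families]
        predictions[(p.grid_y, p.grid_x)] = ens.weighted_ensemble_probs(
            fields, best_w
        )
    smap = slide_map.assemble_score_map(
        predictions, labels.shape, cfg.patch_size, slide_id="toy-slide",
        filtered_cells=filtered_cells,
    )
    slide_map.save_score_map(smap, maps_dir / "toy-slide.tif")
    overlay = slide_map.render_overlay(slide, smap)
    Image.fromarray(overlay).save(maps_dir / "toy-slide_overlay.png")
    Image.fromarray(slide_map.colorbar_strip()).save(maps_dir / "colorbar.png")
    log("done")

    return {
        "config_hash": chash,
        "class_weights": class_weights,
        "metrics": metrics_df,
        "best_weights": best_w.w,
        "grid_table": table,
        "ttest": ttest_df,
        "score_map": smap,
        "n_patches_kept": len(kept),
        "n_patches_total": len(pairs),
        "models": models,
        "histories": None,
    }
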