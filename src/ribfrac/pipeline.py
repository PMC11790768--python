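"""File-based pipeline stages: simulate -> preprocess -> mine -> split ->
train -> predict -> aggregate -> evaluate.

Stages communicate exclusively through files under a working directory, so
any stage can be rerun or inspected in isolation:

    workdir/
      raw/          synthetic PNGs + annotations.csv + manifest.json
      large/        upscaled mining-frame PNGs + annotations_large.csv
      patches/      per-patch PNGs + samples.csv
      splits.csv    group_id,partition(train|val|test),fold
      model/        weights.npz + sidecar.json (config, seed, history)
      predictions/  logits.csv, aggregated.csv
      metrics/      per-level/assessment JSON + confusion CSVs + summary.txt

Every stage validates its configuration before any work starts, writes a
``run_<stage>.json`` manifest (config hash, seed, package version), and
raises an actionable error naming the producing stage when an upstream
artifact is missing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .errors import ConfigError, PipelineError
from .labels import CLASSES, label_index, label_name
from . import synthetic
from .preprocessing import (
    CropSpec,
    UnfoldedImage,
    crop_image,
    load_image,
    save_image,
    to_large_coords,
    upscale_image,
)
from .mining import (
    PatchSample,
    ShiftScheme,
    box_overlap_curation,
    extract_patch,
    mine_fracture_samples,
    negative_window_corners,
)
from .partition import GroupedDataset, check_no_leakage, group_split, split_manifest
from .classifier import (
    ModelConfig,
    PhaseSpec,
    TrainSchedule,
    build_model,
    predict_logits,
    train_two_phase,
)
from .aggregation import LogitGroup, aggregate_group
from .evaluation import ALL_LEVELS, assess_aggregated, assess_standard, score_level, summary_table

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "mine", "split", "train", "predict", "aggregate", "evaluate")


@dataclasses.dataclass
class PipelineConfig:
    """One config object for the whole run; see the module docstring for the
    artifact layout. Nested dicts override the stage defaults."""

    workdir: str = "runs/default"
    seed: int = 0
    simulate: dict = dataclasses.field(default_factory=dict)
    preprocess: dict = dataclasses.field(default_factory=dict)
    mine: dict = dataclasses.field(default_factory=dict)
    split: dict = dataclasses.field(default_factory=dict)
    model: dict = dataclasses.field(default_factory=dict)
    schedule: dict = dataclasses.field(default_factory=dict)

    # -- typed views (validate eagerly) ------------------------------------
    def sim_params(self) -> synthetic.SimulationParams:
        d = dict(self.simulate)
        d.pop("n_positive_images", None)
        d.pop("n_negative_images", None)
        d.setdefault("seed", self.seed)
        return synthetic.SimulationParams(**d)

    @property
    def n_positive_images(self) -> int:
        return int(self.simulate.get("n_positive_images", 10))

    @property
    def n_negative_images(self) -> int:
        return int(self.simulate.get("n_negative_images", 4))

    def crop_spec(self) -> CropSpec | None:
        crop = self.preprocess.get("crop")
        return None if crop is None else CropSpec(**crop)

    @property
    def upscale_factor(self) -> int:
        return int(self.preprocess.get("factor", 3))

    def shift_scheme(self) -> ShiftScheme:
        return ShiftScheme(
            step=int(self.mine.get("shift_step", 10)),
            steps_per_direction=int(self.mine.get("steps_per_direction", 4)),
        )

    @property
    def patch_size(self) -> int:
        return int(self.mine.get("patch_size", 99))

    @property
    def negative_stride(self) -> int:
        return int(self.mine.get("stride", 25))

    @property
    def curation_min_overlap(self) -> float:
        return float(self.mine.get("curation_min_overlap", 0.5))

    def model_config(self) -> ModelConfig:
        d = dict(self.model)
        if "dense_units" in d:
            d["dense_units"] = tuple(d["dense_units"])
        d.setdefault("patch_size", self.patch_size)
        return ModelConfig(**d)

    def train_schedule(self) -> TrainSchedule:
        s = self.schedule
        return TrainSchedule(
            phase1=PhaseSpec(True, float(s.get("lr_phase1", 1e-4)), int(s.get("max_epochs_phase1", 100))),
            phase2=PhaseSpec(False, float(s.get("lr_phase2", 8e-5)), int(s.get("max_epochs_phase2", 100))),
            early_stop_patience=int(s.get("early_stop_patience", 15)),
            plateau_patience=int(s.get("plateau_patience", 2)),
            plateau_factor=float(s.get("plateau_factor", 0.1)),
        )

    def validate(self) -> None:
        """Build every typed view once so bad values fail before any work."""
        self.sim_params()
        self.crop_spec()
        self.shift_scheme()
        self.model_config()
        self.train_schedule()
        if self.upscale_factor < 1:
            raise ConfigError("upscale factor must be >= 1")
        tf = float(self.split.get("test_fraction", 0.30))
        vf = float(self.split.get("val_fraction", 0.15))
        if not (0 < tf < 1 and 0 < vf < 1):
            raise ConfigError("split fractions must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        p = Path(path)
        text = p.read_text()
        if p.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data or {})


def _workdir(cfg: PipelineConfig) -> Path:
    wd = Path(cfg.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    return wd


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path}; run the '{producer}' stage first"
        )
    return path


def _write_manifest(cfg: PipelineConfig, stage: str, extra: dict | None = None) -> None:
    wd = _workdir(cfg)
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    manifest = {
        "stage": stage,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": cfg.seed,
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    with open(wd / f"run_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# --------------------------------------------------------------------------
# stages


def run_simulate(cfg: PipelineConfig) -> dict:
    out = _workdir(cfg) / "raw"
    manifest = synthetic.generate_dataset(
        cfg.sim_params(), cfg.n_positive_images, cfg.n_negative_images, out
    )
    _write_manifest(cfg, "simulate", {"n_images": len(manifest["images"])})
    return manifest


def run_preprocess(cfg: PipelineConfig) -> pd.DataFrame:
    wd = _workdir(cfg)
    raw = _require(wd / "raw" / "manifest.json", "simulate")
    with open(raw) as fh:
        manifest = json.load(fh)
    ann = pd.read_csv(wd / "raw" / "annotations.csv")
    factor = cfg.upscale_factor
    large_dir = wd / "large"
    large_dir.mkdir(exist_ok=True)

    rows = []
    for entry in manifest["images"]:
        img = load_image(wd / "raw" / entry["path"], entry["image_id"], stage="raw")
        spec = cfg.crop_spec()
        if spec is None:
            h, w = img.shape
            spec = CropSpec(0, 0, h, w)  # identity crop: generator emits post-crop geometry
        cropped = crop_image(img, spec)
        large = upscale_image(cropped, factor)
        save_image(large, large_dir / f"{entry['image_id']}.png")
        for r in ann[ann.image_id == entry["image_id"]].itertuples(index=False):
            X, Y = to_large_coords(int(r.x), int(r.y), spec, factor)
            bx0, by0 = to_large_coords(int(r.box_x0), int(r.box_y0), spec, factor)
            bx1, by1 = to_large_coords(int(r.box_x1), int(r.box_y1), spec, factor)
            rows.append(
                {
                    "image_id": r.image_id,
                    "x": X,
                    "y": Y,
                    "label": r.label,
                    "box_x0": bx0,
                    "box_y0": by0,
                    "box_x1": bx1,
                    "box_y1": by1,
                }
            )
    out = pd.DataFrame(rows, columns=synthetic.ANNOTATION_COLUMNS)
    out.to_csv(large_dir / "annotations_large.csv", index=False)
    _write_manifest(cfg, "preprocess", {"factor": factor})
    return out


def run_mine(cfg: PipelineConfig) -> pd.DataFrame:
    wd = _workdir(cfg)
    large_dir = wd / "large"
    _require(large_dir / "annotations_large.csv", "preprocess")
    with open(_require(wd / "raw" / "manifest.json", "simulate")) as fh:
        manifest = json.load(fh)
    ann = pd.read_csv(large_dir / "annotations_large.csv")
    scheme = cfg.shift_scheme()
    curation = box_overlap_curation(cfg.curation_min_overlap)
    size, stride = cfg.patch_size, cfg.negative_stride

    patches_dir = wd / "patches"
    patches_dir.mkdir(exist_ok=True)
    positives: list[PatchSample] = []
    negative_sources: list[tuple[str, tuple[int, int]]] = []
    neg_shapes: dict[str, tuple[int, int]] = {}

    for entry in manifest["images"]:
        img = load_image(large_dir / f"{entry['image_id']}.png", entry["image_id"], stage="large")
        if entry["role"] == "positive":
            anns = synthetic.annotations_from_frame(ann[ann.image_id == entry["image_id"]])
            positives.extend(
                mine_fracture_samples(img, anns, scheme=scheme, curation=curation, size=size)
            )
        else:
            neg_shapes[entry["image_id"]] = img.shape
            for corner in negative_window_corners(img.shape, size, stride):
                negative_sources.append((entry["image_id"], corner))

    # Random balancing: as many negatives as positive samples, drawn
    # uniformly over every sliding-window position of every negative image.
    n_target = min(len(positives), len(negative_sources))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0xBA1]))
    chosen = np.sort(rng.choice(len(negative_sources), size=n_target, replace=False))
    negatives: list[PatchSample] = []
    img_cache: dict[str, UnfoldedImage] = {}
    half = size // 2
    for i in chosen:
        image_id, (r, c) = negative_sources[i]
        if image_id not in img_cache:
            img_cache[image_id] = load_image(
                large_dir / f"{image_id}.png", image_id, stage="large"
            )
        patch = extract_patch(img_cache[image_id], (c + half, r + half), size)
        negatives.append(
            PatchSample(
                patch=patch,
                label="no_fracture",
                image_id=image_id,
                group_id=f"{image_id}_neg_r{r}_c{c}",
                center=(c + half, r + half),
            )
        )

    rows = []
    for s in positives + negatives:
        fname = f"{s.group_id}_dx{s.shift[0]:+d}_dy{s.shift[1]:+d}.png"
        Image.fromarray(s.patch, mode="L").save(patches_dir / fname)
        rows.append(
            {
                "patch_path": fname,
                "image_id": s.image_id,
                "group_id": s.group_id,
                "label": s.label,
                "X": s.center[0],
                "Y": s.center[1],
                "dx": s.shift[0],
                "dy": s.shift[1],
            }
        )
    df = pd.DataFrame(
        rows, columns=["patch_path", "image_id", "group_id", "label", "X", "Y", "dx", "dy"]
    )
    df.to_csv(patches_dir / "samples.csv", index=False)
    _write_manifest(
        cfg,
        "mine",
        {
            "n_positive_samples": len(positives),
            "n_negative_samples": len(negatives),
            "n_negative_windows_total": len(negative_sources),
        },
    )
    return df


def _load_samples(wd: Path, with_patches: bool = True) -> list[PatchSample]:
    patches_dir = wd / "patches"
    df = pd.read_csv(_require(patches_dir / "samples.csv", "mine"))
    samples = []
    for r in df.itertuples(index=False):
        patch = (
            np.asarray(Image.open(patches_dir / r.patch_path).convert("L"))
            if with_patches
            else np.empty((0, 0), dtype=np.uint8)
        )
        samples.append(
            PatchSample(
                patch=patch,
                label=str(r.label),
                image_id=str(r.image_id),
                group_id=str(r.group_id),
                center=(int(r.X), int(r.Y)),
                shift=(int(r.dx), int(r.dy)),
            )
        )
    return samples


def run_split(cfg: PipelineConfig) -> pd.DataFrame:
    wd = _workdir(cfg)
    samples = _load_samples(wd, with_patches=False)
    ds = GroupedDataset.from_samples(samples)
    tf = float(cfg.split.get("test_fraction", 0.30))
    vf = float(cfg.split.get("val_fraction", 0.15))
    tol = cfg.split.get("tolerance", 0.03)
    tol = None if tol is None else float(tol)
    train_all, test = group_split(ds, test_fraction=tf, seed=cfg.seed, tolerance=tol)
    fit, val = group_split(train_all, test_fraction=vf, seed=cfg.seed + 1, tolerance=None)
    check_no_leakage(fit, val, test)
    assignments = {g: ("train", None) for g in fit.group_ids}
    assignments.update({g: ("val", None) for g in val.group_ids})
    assignments.update({g: ("test", None) for g in test.group_ids})
    df = split_manifest(assignments, wd / "splits.csv")
    _write_manifest(
        cfg,
        "split",
        {"n_train": len(fit), "n_val": len(val), "n_test": len(test)},
    )
    return df


def _partition_datasets(wd: Path) -> dict[str, GroupedDataset]:
    splits = pd.read_csv(_require(wd / "splits.csv", "split"))
    part_of = dict(zip(splits.group_id, splits.partition))
    samples = _load_samples(wd, with_patches=True)
    buckets: dict[str, list[PatchSample]] = {"train": [], "val": [], "test": []}
    for s in samples:
        buckets[part_of[s.group_id]].append(s)
    return {k: GroupedDataset.from_samples(v) for k, v in buckets.items()}


def run_train(cfg: PipelineConfig) -> list[dict]:
    wd = _workdir(cfg)
    parts = _partition_datasets(wd)
    model = build_model(cfg.model_config(), seed=cfg.seed)
    model, history = train_two_phase(
        model, parts["train"], parts["val"], cfg.train_schedule(), seed=cfg.seed
    )
    model_dir = wd / "model"
    model_dir.mkdir(exist_ok=True)
    weights = model.get_weights()
    np.savez(model_dir / "weights.npz", **{f"p{i:03d}": w for i, w in enumerate(weights)})
    sidecar = {
        "model": cfg.model.copy(),
        "seed": cfg.seed,
        "history": history,
        "version": __version__,
    }
    with open(model_dir / "sidecar.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    _write_manifest(cfg, "train", {"epochs_run": len(history)})
    return history


def load_trained_model(cfg: PipelineConfig):
    wd = _workdir(cfg)
    weights_path = _require(wd / "model" / "weights.npz", "train")
    model = build_model(cfg.model_config(), seed=cfg.seed)
    with np.load(weights_path) as z:
        model.set_weights([z[k] for k in sorted(z.files)])
    return model


def run_predict(cfg: PipelineConfig) -> pd.DataFrame:
    wd = _workdir(cfg)
    model = load_trained_model(cfg)
    parts = _partition_datasets(wd)
    records = predict_logits(model, parts["test"])
    pred_dir = wd / "predictions"
    pred_dir.mkdir(exist_ok=True)
    rows = []
    for r in records:
        row = {
            "image_id": r.sample.image_id,
            "group_id": r.sample.group_id,
            "true_label": r.true_label,
            "predicted_label": r.predicted_label,
        }
        row.update({f"score_{c}": float(v) for c, v in enumerate(r.scores)})
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(pred_dir / "logits.csv", index=False)
    _write_manifest(cfg, "predict", {"n_records": len(df)})
    return df


def run_aggregate(cfg: PipelineConfig) -> pd.DataFrame:
    wd = _workdir(cfg)
    logits = pd.read_csv(_require(wd / "predictions" / "logits.csv", "predict"))
    score_cols = sorted(c for c in logits.columns if c.startswith("score_"))
    rows = []
    for gid, grp in logits.groupby("group_id", sort=False):
        g = LogitGroup(
            group_id=str(gid),
            labels=grp.predicted_label.to_numpy(),
            score_matrix=grp[score_cols].to_numpy(),
            true_label=int(grp.true_label.iloc[0]),
        )
        agg = aggregate_group(g)
        row = {
            "group_id": agg.group_id,
            "true_label": agg.true_label,
            "Y": agg.Y,
            "final_label": agg.final_label,
        }
        row.update({f"mean_score_{c}": float(v) for c, v in enumerate(agg.mean_scores)})
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(wd / "predictions" / "aggregated.csv", index=False)
    _write_manifest(cfg, "aggregate", {"n_groups": len(df)})
    return df


def run_evaluate(cfg: PipelineConfig) -> dict:
    wd = _workdir(cfg)
    logits = pd.read_csv(_require(wd / "predictions" / "logits.csv", "predict"))
    agg = pd.read_csv(_require(wd / "predictions" / "aggregated.csv", "aggregate"))
    metrics_dir = wd / "metrics"
    metrics_dir.mkdir(exist_ok=True)
    reports = []
    for level in ALL_LEVELS:
        reports.append(
            score_level(
                logits.true_label.to_numpy(),
                logits.predicted_label.to_numpy(),
                level,
                assessment="standard",
            )
        )
        reports.append(
            score_level(
                agg.true_label.to_numpy(),
                agg.final_label.to_numpy(),
                level,
                assessment="aggregated",
            )
        )
    out = {}
    for r in reports:
        key = f"{r.level}_{r.assessment}"
        with open(metrics_dir / f"{key}.json", "w") as fh:
            json.dump(r.to_dict(), fh, indent=2)
        pd.DataFrame(r.confusion_abs, index=list(r.row_names), columns=list(r.col_names)).to_csv(
            metrics_dir / f"confusion_{key}.csv"
        )
        out[key] = r.to_dict()
    (metrics_dir / "summary.txt").write_text(summary_table(reports) + "\n")
    _write_manifest(cfg, "evaluate", {"reports": sorted(out)})
    return out


_STAGE_FUNCS = {
    "simulate": run_simulate,
    "preprocess": run_preprocess,
    "mine": run_mine,
    "split": run_split,
    "train": run_train,
    "predict": run_predict,
    "aggregate": run_aggregate,
    "evaluate": run_evaluate,
}


def run_subcommand(name: str, cfg: PipelineConfig):
    """Run one named stage, or ``all`` to chain every stage end to end."""
    cfg.validate()
    if name == "all":
        result = None
        for stage in STAGES:
            logger.info("stage %s", stage)
            result = _STAGE_FUNCS[stage](cfg)
        return result
    if name not in _STAGE_FUNCS:
        raise ConfigError(f"unknown stage {name!r}; expected one of {STAGES + ('all',)}")
    return _STAGE_FUNCS[name](cfg)
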