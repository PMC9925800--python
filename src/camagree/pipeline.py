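"""End-to-end orchestration of the CAM-reliability experiment.

Six resumable stages, mirroring the experimental design of a CAM
reliability study:

1. ``generate`` -- synthesise the dataset (paired fresh/damaged stacks with
   ground-truth damage masks and liquid loss) and the leakage-free
   sample-level split;
2. ``train`` -- fit each configured CNN architecture to classify fresh
   (y=0) vs damaged (y=1) slices;
3. ``cam`` -- compute heatmaps for every (model, CAM method, damaged slice)
   for the damaged class;
4. ``agree`` -- binarise the heatmaps over the t_CAM grid and compute mIoU
   against the ground-truth masks, the cross-method agreement phi_m, the
   cross-model agreement phi_c, and the liquid-loss correlation;
5. ``report`` -- summarise medians/IQRs, run the Kruskal-Wallis group
   tests and write ``summary.json`` plus overlay renderings.

Each stage writes its artifacts (HDF5 / CSV / JSON) into the output
directory together with a manifest recording seeds, stage config hashes
and artifact checksums; a stage is skipped on re-run when its config hash
matches an existing artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import backend, cam, preprocess, synthetic
from .exceptions import ConfigurationError

__all__ = ["RunConfig", "run_pipeline", "load_config", "STAGES"]

log = logging.getLogger("camagree")

STAGES = ("generate", "train", "cam", "agree", "report")

DEFAULT_TCAM_GRID = tuple(np.round(np.arange(0.1, 0.95, 0.1), 1))


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    mask_background: bool = True        # zero background pixels before train/CAM
    generator: synthetic.GeneratorConfig = field(default_factory=synthetic.GeneratorConfig)
    foreground: preprocess.ForegroundConfig = field(default_factory=preprocess.ForegroundConfig)
    split_fractions: tuple = (0.8, 0.1, 0.1)
    architectures: tuple = (("plain", 0), ("residual", 1), ("branch", 2))
    train: backend.TrainConfig = field(default_factory=backend.TrainConfig)
    cam_methods: tuple = ("gradcam", "gradcampp", "scorecam", "faster_scorecam", "layercam")
    t_cam_grid: tuple = DEFAULT_TCAM_GRID
    reference_t_cam: float = 0.5        # threshold used for mIoU/correlation headlines
    class_index: int = 1
    layer_cam_mode: str = "paper"
    both_empty: str = "one"
    augment_training: bool = False      # contrast/geometry copies of the train set
    model_width: int = 12
    out_dir: str = "runs/default"
    seed: int = 0

    def __post_init__(self):
        if len(self.architectures) < 1:
            raise ConfigurationError("need at least one architecture")
        if len(self.cam_methods) < 2:
            raise ConfigurationError("need at least two CAM methods for phi_m")
        unknown = set(self.cam_methods) - set(cam.CAM_METHODS)
        if unknown:
            raise ConfigurationError(f"unknown CAM methods: {sorted(unknown)}")
        if any(not 0.0 < t < 1.0 for t in self.t_cam_grid):
            raise ConfigurationError("t_CAM values must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Config file I/O
# ---------------------------------------------------------------------------

def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file of nested sections."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    if "generator" in kwargs:
        gen = dict(kwargs["generator"])
        if "texture_params" in gen:
            gen["texture_params"] = synthetic.TextureParams(**gen["texture_params"])
        if "ll_coupling" in gen:
            gen["ll_coupling"] = synthetic.LLCoupling(**gen["ll_coupling"])
        if "treatment_levels" in gen:
            gen["treatment_levels"] = tuple(gen["treatment_levels"])
        if isinstance(gen.get("n_samples_per_group"), list):
            gen["n_samples_per_group"] = tuple(gen["n_samples_per_group"])
        kwargs["generator"] = synthetic.GeneratorConfig(**gen)
    if "foreground" in kwargs:
        kwargs["foreground"] = preprocess.ForegroundConfig(**kwargs["foreground"])
    if "train" in kwargs:
        kwargs["train"] = backend.TrainConfig(**kwargs["train"])
    for key in ("split_fractions", "cam_methods", "t_cam_grid"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "architectures" in kwargs:
        kwargs["architectures"] = tuple((a, int(s)) for a, s in kwargs["architectures"])
    return RunConfig(**kwargs)


def _cfg_hash(obj) -> str:
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


class _Manifest:
    def __init__(self, out: Path):
        self.path = out / "manifest.json"
        self.data = json.loads(self.path.read_text()) if self.path.exists() else {
            "stages": {}, "created": time.strftime("%Y-%m-%dT%H:%M:%S")
        }

    def fresh(self, stage: str, cfg_hash: str, artifacts) -> bool:
        rec = self.data["stages"].get(stage)
        return bool(rec and rec["config_hash"] == cfg_hash
                    and all(Path(a).exists() for a in rec["artifacts"]))

    def record(self, stage: str, cfg_hash: str, artifacts, extra=None):
        self.data["stages"][stage] = {
            "config_hash": cfg_hash,
            "artifacts": [str(a) for a in artifacts],
            "checksums": {Path(a).name: _file_hash(Path(a)) for a in artifacts},
            "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
            **(extra or {}),
        }
        self.path.write_text(json.dumps(self.data, indent=2))


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _partition_arrays(samples, split, mask_background=True):
    """Stack slice images/labels per partition (both classes, leakage-free).

    With ``mask_background`` (the study protocol) every slice is multiplied
    by its foreground mask, so the classifier never sees background pixels.
    """
    parts = {p: ([], []) for p in preprocess.PARTITIONS}
    for s in samples:
        part = split.partition_of(s.sample_id)
        for sl in s.fresh_slices + s.damaged_slices:
            img = sl.image
            if mask_background:
                img = img * s.foreground_masks[sl.slice_index]
            parts[part][0].append(img)
            parts[part][1].append(sl.y)
    return {
        p: (np.stack(imgs) if imgs else np.zeros((0, 1, 1)), np.asarray(ys, dtype=int))
        for p, (imgs, ys) in parts.items()
    }


def _augmented_training_set(samples, split, seed, mask_background=True):
    rng = np.random.default_rng(seed)
    imgs, ys = [], []
    for s in samples:
        if split.partition_of(s.sample_id) != "train":
            continue
        for sl in s.fresh_slices + s.damaged_slices:
            src = sl
            if mask_background:
                src = synthetic.SliceImage(
                    sl.image * s.foreground_masks[sl.slice_index],
                    sl.sample_id, sl.slice_index, sl.y, sl.treatment_level)
            imgs.append(src.image)
            ys.append(src.y)
            for aug in preprocess.augment(src, rng):
                imgs.append(aug.image)
                ys.append(aug.y)
    return np.stack(imgs), np.asarray(ys, dtype=int)


def stage_generate(cfg: RunConfig, out: Path, manifest: _Manifest):
    h = _cfg_hash({"generator": cfg.generator, "split": cfg.split_fractions,
                   "seed": cfg.seed})
    dataset_path = out / "dataset.h5"
    split_path = out / "split.json"
    if manifest.fresh("generate", h, [dataset_path, split_path]):
        log.info("generate: cached")
        return synthetic.load_hdf5(dataset_path), _load_split(split_path)
    log.info("generate: %d groups", len(cfg.generator.treatment_levels))
    samples = synthetic.generate_dataset(cfg.generator)
    split = preprocess.split_by_sample(samples, cfg.split_fractions, seed=cfg.seed)
    synthetic.save_hdf5(samples, dataset_path)
    split_path.write_text(json.dumps(split.assignment, indent=2))
    manifest.record("generate", h, [dataset_path, split_path],
                    {"n_samples": len(samples)})
    return samples, split


def _load_split(path: Path) -> preprocess.SplitAssignment:
    return preprocess.SplitAssignment(json.loads(path.read_text()))


def stage_train(cfg: RunConfig, out: Path, manifest: _Manifest, samples, split):
    h = _cfg_hash({"architectures": cfg.architectures, "train": cfg.train,
                   "width": cfg.model_width, "augment": cfg.augment_training,
                   "upstream": manifest.data["stages"]["generate"]["config_hash"]})
    model_dir = out / "models"
    model_dir.mkdir(exist_ok=True)
    stems = {a: model_dir / f"{a}_{s}" for a, s in cfg.architectures}
    artifacts = [p.with_suffix(".npz") for p in stems.values()]
    acc_path = out / "accuracy.csv"
    if manifest.fresh("train", h, artifacts + [acc_path]):
        log.info("train: cached")
        return {a: backend.BackendModel.load(stems[a]) for a, _ in cfg.architectures}

    parts = _partition_arrays(samples, split, cfg.mask_background)
    if cfg.augment_training:
        train_set = _augmented_training_set(samples, split, cfg.seed, cfg.mask_background)
    else:
        train_set = parts["train"]
    models, rows = {}, []
    for arch, arch_seed in cfg.architectures:
        log.info("train: %s (seed %d) on %d images", arch, arch_seed, len(train_set[1]))
        model = backend.build_model(arch, seed=arch_seed,
                                    width=cfg.model_width).astype(np.float32)
        result = backend.train(model, train_set, parts["val"], cfg.train, seed=arch_seed)
        pd.DataFrame(result.history).to_csv(model_dir / f"{arch}_{arch_seed}_log.csv",
                                            index=False)
        model.save(stems[arch])
        models[arch] = model
        for part in preprocess.PARTITIONS:
            x, y = parts[part]
            rows.append({"model": arch, "split": part,
                         "accuracy": backend.evaluate_accuracy(model, x, y)
                         if len(y) else float("nan")})
    pd.DataFrame(rows).to_csv(acc_path, index=False)
    manifest.record("train", h, artifacts + [acc_path])
    return models


def _damaged_slices(samples):
    for s in samples:
        for i, sl in enumerate(s.damaged_slices):
            yield s, i, sl


def stage_cam(cfg: RunConfig, out: Path, manifest: _Manifest, samples, models):
    import h5py

    h = _cfg_hash({"methods": cfg.cam_methods, "mode": cfg.layer_cam_mode,
                   "class": cfg.class_index,
                   "upstream": manifest.data["stages"]["train"]["config_hash"]})
    path = out / "heatmaps.h5"
    if manifest.fresh("cam", h, [path]):
        log.info("cam: cached")
        return path
    n = 0
    with h5py.File(path, "w") as f:
        for arch in models:
            for method in cfg.cam_methods:
                for s, i, sl in _damaged_slices(samples):
                    kwargs = {"mode": cfg.layer_cam_mode} if method == "layercam" else {}
                    img = sl.image * s.foreground_masks[i] if cfg.mask_background else sl.image
                    heat = cam.compute_cam(method, models[arch], img,
                                           class_index=cfg.class_index, **kwargs)
                    if heat.values.max() == 0:
                        log.warning("all-zero heatmap: %s/%s %s slice %d",
                                    arch, method, s.sample_id, i)
                    ds = f.create_dataset(f"{arch}/{method}/{s.sample_id}/{i}",
                                          data=heat.values.astype(np.float32))
                    ds.attrs.update({"model": arch, "method": method,
                                     "sample": s.sample_id, "slice": i,
                                     "class_index": cfg.class_index})
                    n += 1
                log.info("cam: %s/%s done", arch, method)
    manifest.record("cam", h, [path], {"n_heatmaps": n})
    return path


def stage_agree(cfg: RunConfig, out: Path, manifest: _Manifest, samples, heatmap_path):
    import h5py

    h = _cfg_hash({"tcam": cfg.t_cam_grid, "ref": cfg.reference_t_cam,
                   "both_empty": cfg.both_empty,
                   "upstream": manifest.data["stages"]["cam"]["config_hash"]})
    paths = {name: out / f"{name}.csv" for name in ("miou", "phi", "correlation")}
    if manifest.fresh("agree", h, list(paths.values())):
        log.info("agree: cached")
        return {k: pd.read_csv(p) for k, p in paths.items()}

    by_sample = {s.sample_id: s for s in samples}
    with h5py.File(heatmap_path, "r") as f:
        archs = list(f.keys())
        methods = list(cfg.cam_methods)
        heat = {
            (a, m, sid, int(i)): np.asarray(f[a][m][sid][i])
            for a in archs for m in methods
            for sid in f[a][m] for i in f[a][m][sid]
        }

    grid = [float(t) for t in cfg.t_cam_grid]
    masks = {}
    for (a, m, sid, i), values in heat.items():
        fg = by_sample[sid].foreground_masks[i]
        for t in grid:
            masks[(a, m, sid, i, t)] = cam.binarize(values, t, foreground=fg)

    slice_keys = sorted({(sid, i) for (_, _, sid, i) in heat})

    miou_rows = []
    for a in archs:
        for m in methods:
            for t in grid:
                pred = [masks[(a, m, sid, i, t)] for sid, i in slice_keys]
                truth = [by_sample[sid].truth_masks[i] for sid, i in slice_keys]
                miou_rows.append({"model": a, "method": m, "t_cam": t,
                                  "miou": agr.mean_iou(pred, truth)})

    phi_rows = []
    for t in grid:
        for a in archs:
            for sid, i in slice_keys:
                rec = agr.agreement_across_cams(
                    {m: masks[(a, m, sid, i, t)] for m in methods},
                    model_id=a, slice_id=f"{sid}/{i}", t_cam=t,
                    both_empty=cfg.both_empty)
                phi_rows.append({"kind": "phi_m", "fixed": a, "sample": sid,
                                 "slice": i, "t_cam": t, "value": rec.value,
                                 "n_pairs": rec.n_pairs})
        if len(archs) >= 2:
            for m in methods:
                for sid, i in slice_keys:
                    rec = agr.agreement_across_models(
                        {a: masks[(a, m, sid, i, t)] for a in archs},
                        method_id=m, slice_id=f"{sid}/{i}", t_cam=t,
                        both_empty=cfg.both_empty)
                    phi_rows.append({"kind": "phi_c", "fixed": m, "sample": sid,
                                     "slice": i, "t_cam": t, "value": rec.value,
                                     "n_pairs": rec.n_pairs})

    corr_rows = []
    t_ref = float(cfg.reference_t_cam)
    sample_ids = sorted(by_sample)
    ll = [by_sample[sid].liquid_loss_pct for sid in sample_ids]
    for a in archs:
        for m in methods:
            per_sample = []
            for sid in sample_ids:
                s = by_sample[sid]
                fracs = [
                    agr.damage_fraction(masks[(a, m, sid, i, t_ref)],
                                        s.foreground_masks[i])
                    for i in range(len(s.damaged_slices))
                ]
                per_sample.append(float(np.mean(fracs)))
            res = agr.correlate_with_liquid_loss(per_sample, ll)
            corr_rows.append({"model": a, "method": m, "rho": res.coefficient,
                              "p_value": res.p_value, "n": res.n,
                              "shapiro_p": res.shapiro_p,
                              "undefined": res.undefined})

    tables = {"miou": pd.DataFrame(miou_rows), "phi": pd.DataFrame(phi_rows),
              "correlation": pd.DataFrame(corr_rows)}
    for k, df in tables.items():
        df.to_csv(paths[k], index=False)
    # reload from disk so fresh and cached runs see bit-identical tables
    tables = {k: pd.read_csv(p) for k, p in paths.items()}
    manifest.record("agree", h, list(paths.values()),
                    {"pair_counts": {"phi_m": len(methods) * (len(methods) - 1) // 2,
                                     "phi_c": len(archs) * (len(archs) - 1) // 2}})
    return tables


def _overlay_png(image, heat, path):
    import imageio.v3 as iio

    img = np.clip(np.asarray(image, dtype=float), 0, 1)
    h = np.clip(np.asarray(heat, dtype=float), 0, 1)
    rgb = np.stack([img * (1 - h) + h, img * (1 - h), img * (1 - h)], axis=-1)
    iio.imwrite(path, (rgb * 255).astype(np.uint8))


def stage_report(cfg: RunConfig, out: Path, manifest: _Manifest, samples,
                 tables, heatmap_path):
    import h5py

    h = _cfg_hash({"upstream": manifest.data["stages"]["agree"]["config_hash"]})
    summary_path = out / "summary.json"

    t_ref = float(cfg.reference_t_cam)
    phi = tables["phi"]
    at_ref = phi[np.isclose(phi["t_cam"], t_ref)]

    def _dist(df):
        v = df["value"].dropna()
        return {"median": float(v.median()), "iqr": float(v.quantile(0.75) - v.quantile(0.25)),
                "n": int(v.size)}

    phi_m = at_ref[at_ref["kind"] == "phi_m"]
    phi_c = at_ref[at_ref["kind"] == "phi_c"]
    summary = {
        "t_cam_reference": t_ref,
        "accuracy": pd.read_csv(out / "accuracy.csv").to_dict("records"),
        "phi_m_by_model": {a: _dist(g) for a, g in phi_m.groupby("fixed")},
        "phi_c_by_method": {m: _dist(g) for m, g in phi_c.groupby("fixed")},
        "miou_at_reference": tables["miou"][
            np.isclose(tables["miou"]["t_cam"], t_ref)].to_dict("records"),
        "liquid_loss_correlation": tables["correlation"].to_dict("records"),
    }
    if phi_m["fixed"].nunique() >= 2:
        stat, p = agr.compare_groups(
            {a: g["value"].dropna().to_list() for a, g in phi_m.groupby("fixed")})
        summary["kruskal_phi_m_across_models"] = {"H": stat, "p_value": p}
    if not phi_c.empty and phi_c["fixed"].nunique() >= 2:
        stat, p = agr.compare_groups(
            {m: g["value"].dropna().to_list() for m, g in phi_c.groupby("fixed")})
        summary["kruskal_phi_c_across_methods"] = {"H": stat, "p_value": p}

    overlays = out / "overlays"
    overlays.mkdir(exist_ok=True)
    with h5py.File(heatmap_path, "r") as f:
        first_sample = samples[0]
        for a in f:
            for m in f[a]:
                key = f"{a}/{m}/{first_sample.sample_id}/0"
                if key in f:
                    _overlay_png(first_sample.damaged_slices[0].image,
                                 np.asarray(f[key]),
                                 overlays / f"{a}_{m}.png")

    summary_path.write_text(json.dumps(summary, indent=2))
    manifest.record("report", h, [summary_path])
    return summary


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig, stages=STAGES) -> dict:
    """Run the requested stages in order; returns the summary (if computed).

    Stage artifacts are cached in ``cfg.out_dir`` keyed by config hashes, so
    a re-run with an unchanged config resumes from existing files.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    requested = [s for s in STAGES if s in stages]
    samples, split = stage_generate(cfg, out, manifest)
    if requested == ["generate"]:
        return {"n_samples": len(samples), "split": split.sizes()}
    models = stage_train(cfg, out, manifest, samples, split)
    if set(requested) <= {"generate", "train"}:
        return {"models": sorted(models)}
    heatmap_path = stage_cam(cfg, out, manifest, samples, models)
    if "agree" not in requested and "report" not in requested:
        return {"heatmaps": str(heatmap_path)}
    tables = stage_agree(cfg, out, manifest, samples, heatmap_path)
    if "report" not in requested:
        return {k: len(v) for k, v in tables.items()}
    return stage_report(cfg, out, manifest, samples, tables, heatmap_path)
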