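"""End-to-end orchestration with config, caching, and a run manifest.

A single YAML config drives all stages; every stochastic element derives its
seed from the one master seed.  Each stage writes its artifacts under the
output directory and records a content stamp (hash of its config slice and
its upstream stamp) in the run manifest; re-running with an unchanged config
reuses cached stage outputs.

Stage order: synth -> sample -> features -> train-eval -> select ->
retrain on selected -> map -> extent.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .features import compute_descriptors_at, family_feature_names
from .imagery import load_series, read_geometry, write_geometry, write_raster
from .mapping import classify_raster, zone_extent_stats
from .model_eval import HabitatClassificationModel, RFConfig
from .sampling import GroundTruthSet, assemble_ground_truth
from .selection import SelectionConfig, select_features
from .synthetic import SceneConfig, generate_scene_series

STAGES = ("synth", "sample", "features", "train-eval", "select", "map", "extent")

DEFAULT_CONFIG = {
    "seed": 0,
    "scene": {"height": 256, "width": 256, "n_plots": 5, "n_shrub_points": 30,
              "n_bare_points": 12, "transect_count": 40, "n_shrub_blobs": 4,
              "n_bare_patches": 3},
    "sampling": {"radius_m": 0.5},
    "features": {"families": ["spectral", "texture", "morphology"]},
    "model": {"n_trees": 200},
    "selection": {"enabled": False, "n_trees": 60, "n_forests_ranking": 10,
                  "n_forests_trajectory": 5},
    "map": {"enabled": False, "threshold": 0.6, "tile": 128,
            "families": ["spectral"]},
}


def load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


class _Manifest:
    def __init__(self, out_dir: Path) -> None:
        self.path = out_dir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"version": __version__, "stages": {}}

    def fresh(self, stage: str, stamp: str, outputs: list[Path]) -> bool:
        rec = self.data["stages"].get(stage)
        return (
            rec is not None
            and rec["stamp"] == stamp
            and all(Path(p).exists() for p in rec["outputs"])
            and rec["outputs"] == [str(p) for p in outputs]
        )

    def record(self, stage: str, stamp: str, outputs: list[Path], dt: float) -> None:
        self.data["stages"][stage] = {
            "stamp": stamp,
            "outputs": [str(p) for p in outputs],
            "seconds": round(dt, 3),
        }
        self.path.write_text(json.dumps(self.data, indent=1))


def run_pipeline(
    config: str | Path | dict, out_dir: str | Path, upto: str = "extent"
) -> dict:
    """Run the pipeline through stage ``upto``; returns artifact paths/results."""
    if upto not in STAGES and upto != "run-all":
        raise ValueError(f"unknown stage {upto}")
    upto_idx = len(STAGES) - 1 if upto == "run-all" else STAGES.index(upto)
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    seed = int(cfg["seed"])
    artifacts: dict = {"out_dir": str(out)}

    # ---- synth -----------------------------------------------------------
    stamp = _hash({"scene": cfg["scene"], "seed": seed})
    scene_cfg = SceneConfig(seed=seed, **cfg["scene"])
    geom_path = out / "geometry.geojson"
    label_path = out / "labels.tif"
    date_paths = [out / f"series_{d}.tif" for d in scene_cfg.dates]
    outputs = [geom_path, label_path] + date_paths
    if not manifest.fresh("synth", stamp, outputs):
        t0 = time.time()
        series, geometry, labels = generate_scene_series(scene_cfg)
        for p, r in zip(date_paths, series.rasters):
            write_raster(p, r, series.geotransform, gsd=series.gsd)
        write_raster(label_path, labels, series.geotransform, gsd=series.gsd)
        write_geometry(geom_path, geometry)
        manifest.record("synth", stamp, outputs, time.time() - t0)
    series = load_series(date_paths, list(scene_cfg.dates))
    geometry = read_geometry(geom_path)
    artifacts["series"] = [str(p) for p in date_paths]
    artifacts["geometry"] = str(geom_path)
    if upto_idx < 1:
        return artifacts

    # ---- sample ----------------------------------------------------------
    stamp = _hash({"up": stamp, "sampling": cfg["sampling"]})
    gt_path = out / "gt_samples.csv"
    if not manifest.fresh("sample", stamp, [gt_path]):
        t0 = time.time()
        gt = assemble_ground_truth(
            geometry, series,
            radius_m=float(cfg["sampling"].get("radius_m", 0.5)),
            transect_count=cfg["sampling"].get(
                "transect_count", scene_cfg.transect_count
            ),
        )
        gt.samples.to_csv(gt_path, index=False)
        manifest.record("sample", stamp, [gt_path], time.time() - t0)
    import pandas as pd

    gt = GroundTruthSet(pd.read_csv(gt_path, dtype={"unit": str}))
    artifacts["gt_samples"] = str(gt_path)
    if upto_idx < 2:
        return artifacts

    # ---- features --------------------------------------------------------
    families = tuple(cfg["features"]["families"])
    stamp = _hash({"up": stamp, "features": cfg["features"]})
    feat_path = out / "features.npz"
    if not manifest.fresh("features", stamp, [feat_path]):
        t0 = time.time()
        stack = compute_descriptors_at(series, gt.pixels, families)
        np.savez_compressed(feat_path, values=stack.values,
                            names=np.asarray(stack.names))
        manifest.record("features", stamp, [feat_path], time.time() - t0)
    data = np.load(feat_path, allow_pickle=False)
    X, names = data["values"], [str(n) for n in data["names"]]
    artifacts["features"] = str(feat_path)
    if upto_idx < 3:
        return artifacts

    # ---- train-eval ------------------------------------------------------
    stamp = _hash({"up": stamp, "model": cfg["model"]})
    metrics_path = out / "metrics.json"
    confusion_path = out / "confusion.csv"
    rf_config = RFConfig(n_trees=int(cfg["model"].get("n_trees", 200)), seed=seed)
    model = HabitatClassificationModel(X, gt, names, rf_config)
    if not manifest.fresh("train-eval", stamp, [metrics_path, confusion_path]):
        t0 = time.time()
        results = model.fit(seed=seed)
        results.confusion_frame().to_csv(confusion_path)
        metrics_path.write_text(json.dumps({
            "schema_version": 1,
            "seed": seed,
            "D": len(names),
            "n_samples": len(gt),
            "metrics": results.metrics.rounded(),
            "oa_exact": results.metrics.oa,
            "kappa_exact": results.metrics.kappa,
        }, indent=1))
        manifest.record(
            "train-eval", stamp, [metrics_path, confusion_path], time.time() - t0
        )
    artifacts["metrics"] = str(metrics_path)
    artifacts["confusion"] = str(confusion_path)
    if upto_idx < 4:
        return artifacts

    # ---- select ----------------------------------------------------------
    sel_cfg = cfg["selection"]
    selected_names = names
    if sel_cfg.get("enabled", False):
        stamp = _hash({"up": stamp, "selection": sel_cfg})
        sel_path = out / "selection.json"
        if not manifest.fresh("select", stamp, [sel_path]):
            t0 = time.time()
            res = select_features(X, gt.samples["class"].to_numpy(), names,
                                  SelectionConfig(
                                      n_forests_ranking=int(sel_cfg.get("n_forests_ranking", 10)),
                                      n_forests_trajectory=int(sel_cfg.get("n_forests_trajectory", 5)),
                                      n_trees=int(sel_cfg.get("n_trees", 60)),
                                      seed=seed,
                                  ))
            sel_path.write_text(json.dumps(res.to_dict(), indent=1))
            manifest.record("select", stamp, [sel_path], time.time() - t0)
        sel = json.loads(sel_path.read_text())
        if sel["prediction_set"]:
            selected_names = sel["prediction_set"]
        artifacts["selection"] = str(sel_path)
    if upto_idx < 5:
        return artifacts

    # ---- map (retrain on deployment feature set, dense inference) --------
    map_cfg = cfg["map"]
    if map_cfg.get("enabled", False):
        if not sel_cfg.get("enabled", False):
            map_fams = tuple(map_cfg.get("families", ["spectral"]))
            selected_names = [
                f"{d}_{n}" for d in series.dates
                for n in family_feature_names(map_fams)
            ]
        stamp = _hash({"up": stamp, "map": map_cfg, "spec": selected_names})
        map_paths = [out / "map_labels.tif", out / "map_confidence.tif",
                     out / "map_mask.tif", out / "zone_report.csv"]
        if not manifest.fresh("map", stamp, map_paths):
            t0 = time.time()
            idx = [names.index(n) for n in selected_names]
            from .model_eval import train_rf

            est = train_rf(X[:, idx], gt.samples["class"].to_numpy(), rf_config)
            hmap = classify_raster(
                series, est, selected_names,
                tile_size=int(map_cfg.get("tile", 128)),
                threshold=float(map_cfg.get("threshold", 0.6)),
            )
            write_raster(map_paths[0], hmap.label_idx, series.geotransform)
            write_raster(
                map_paths[1], hmap.confidence.astype(np.float32), series.geotransform
            )
            write_raster(
                map_paths[2],
                hmap.low_confidence_mask.astype(np.uint8),
                series.geotransform,
            )
            report = zone_extent_stats(hmap, geometry.zones)
            report.to_csv(map_paths[3])
            manifest.record("map", stamp, map_paths, time.time() - t0)
        artifacts["map"] = str(map_paths[0])
        artifacts["zone_report"] = str(map_paths[3])
    return artifacts
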