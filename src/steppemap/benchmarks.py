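"""Reproducible benchmark runners used by the test suite and the acceptance
script.

Three studies, all fully determined by their seeds:

* :func:`run_end_to_end` -- the default synthetic scene at study-scale sample
  counts, combined 444-feature descriptors, grouped leave-one-unit-out CV;
* :func:`seasonality_comparison` -- all-dates vs best single-date pooled CV
  accuracy on a scaled-down scene, repeated over several seeds;
* :func:`selection_benchmark` -- the planted-feature recovery study for the
  two-step feature selection.

Problem sizes are the package's desk-scale defaults: the scaled-down scene is
384 x 384 px with 6 survey plots sampled at 0.2 m radius, and the end-to-end
forests use 128 trees (pooled metrics are insensitive to ensemble size beyond
~100 trees; see the methods note).
"""

from __future__ import annotations

import numpy as np

from .features import compute_descriptors_at
from .model_eval import HabitatClassificationModel, RFConfig
from .sampling import assemble_ground_truth
from .selection import SelectionConfig, select_features
from .synthetic import SceneConfig, generate_scene_series, planted_feature_benchmark


def scaled_scene_config(seed: int) -> SceneConfig:
    """Reduced scene for repeated-seed comparisons (same structure, smaller n)."""
    return SceneConfig(
        height=384, width=384, n_plots=6, n_shrub_points=60, n_bare_points=20,
        transect_count=70, n_shrub_blobs=5, n_bare_patches=4,
        shrub_radius_px=(20, 40), bare_radius_px=(10, 20), min_spacing_m=3.0,
        seed=seed,
    )


def run_end_to_end(
    seed: int = 1,
    scene_config: SceneConfig | None = None,
    n_trees: int = 128,
    radius_m: float = 0.5,
    families=("spectral", "texture", "morphology"),
) -> dict:
    """Full pipeline on one scene: generate, sample, describe, grouped CV."""
    cfg = scene_config if scene_config is not None else SceneConfig(seed=seed)
    series, geometry, _ = generate_scene_series(cfg)
    gt = assemble_ground_truth(
        geometry, series, radius_m=radius_m, transect_count=cfg.transect_count
    )
    stack = compute_descriptors_at(series, gt.pixels, families)
    X = stack.values.astype(np.float32)
    model = HabitatClassificationModel(
        X, gt, stack.names, RFConfig(n_trees=n_trees, seed=seed)
    )
    results = model.fit(seed=seed)
    return {
        "results": results,
        "metrics": results.metrics,
        "gt": gt,
        "stack_names": stack.names,
        "X": X,
        "series": series,
        "geometry": geometry,
        "D": stack.D,
        "n": len(gt),
    }


def seasonality_comparison(
    seeds=(0, 1, 2, 3, 4), n_trees: int = 64, radius_m: float = 0.2
) -> dict:
    """All-dates vs single-date pooled CV OA on the scaled scene, per seed.

    Returns per-seed OAs and the number of seeds on which the time-series
    model strictly beats the best single-date model.
    """
    records = []
    for seed in seeds:
        cfg = scaled_scene_config(seed)
        series, geometry, _ = generate_scene_series(cfg)
        gt = assemble_ground_truth(
            geometry, series, radius_m=radius_m, transect_count=cfg.transect_count
        )
        stack = compute_descriptors_at(series, gt.pixels)
        X = stack.values.astype(np.float32)
        rf = RFConfig(n_trees=n_trees, seed=seed)
        oa_all = (
            HabitatClassificationModel(X, gt, stack.names, rf)
            .fit(seed=seed).metrics.oa
        )
        d = stack.D // series.T
        single = []
        for t in range(series.T):
            Xd = X[:, t * d : (t + 1) * d]
            names_d = stack.names[t * d : (t + 1) * d]
            single.append(
                HabitatClassificationModel(Xd, gt, names_d, rf)
                .fit(seed=seed).metrics.oa
            )
        records.append(
            {"seed": seed, "oa_all_dates": oa_all, "oa_single": single,
             "win": oa_all > max(single)}
        )
    return {
        "records": records,
        "wins": sum(r["win"] for r in records),
        "n_seeds": len(records),
    }


def selection_benchmark(
    seeds=tuple(range(20)),
    n: int = 500,
    d_informative: int = 5,
    d_noise: int = 50,
    config_factory=None,
) -> dict:
    """Planted-feature recovery of the two-step selection over many seeds.

    Recovery counts informative features in the interpretation set (the
    "find all relevant" step); the reported final set size is the prediction
    set (the parsimony step).
    """
    if config_factory is None:
        config_factory = lambda s: SelectionConfig(seed=s)
    records = []
    for seed in seeds:
        X, y, informative = planted_feature_benchmark(
            n, d_informative, d_noise, seed=seed
        )
        res = select_features(X.to_numpy(), y, list(X.columns), config_factory(seed))
        records.append({
            "seed": seed,
            "recovered": len(set(res.interpretation_set) & set(informative)),
            "recovered_prediction": len(set(res.prediction_set) & set(informative)),
            "final_size": len(res.prediction_set),
            "noise_selected": sum(
                n_.startswith("noise_") for n_ in res.prediction_set
            ),
        })
    rec = [r["recovered"] for r in records]
    return {
        "records": records,
        "n_seeds": len(records),
        "seeds_recovering_4plus": sum(v >= d_informative - 1 for v in rec),
        "recovery_rate": float(np.mean(rec)) / d_informative if d_informative else 0.0,
        "max_final_size": max(r["final_size"] for r in records),
        "mean_final_size": float(np.mean([r["final_size"] for r in records])),
    }
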