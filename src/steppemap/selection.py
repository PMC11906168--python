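"""Two-step random-forest feature selection (VSURF-style).

The procedure builds ensembles of random forests and uses their nonparametric
importance statistics in three nested stages:

1. *threshold* -- features are ranked by permutation importance averaged over
   independent forest replicates; a data-driven threshold (the minimum of a
   piecewise-constant regression-tree fit to the importance standard
   deviations over ranks) discards features indistinguishable from noise;
2. *interpretation* -- nested forests over growing ranked prefixes; the
   smallest prefix whose OOB error is within one standard deviation of the
   minimum is kept (tolerates correlated but relevant features);
3. *prediction* -- greedy forward addition in interpretation order; a feature
   enters only if it lowers OOB error by more than the typical OOB
   fluctuation, eliminating redundant copies.

Importance here is held-out permutation importance: each replicate fits a
forest on a bootstrap-style 70/30 split and permutes columns on the held-out
part.  This keeps the statistic nonparametric and conditional on the forest
while staying fast enough for many-seed benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeRegressor


@dataclass
class SelectionConfig:
    n_forests_ranking: int = 20
    n_forests_trajectory: int = 10
    n_trees: int = 100
    holdout_frac: float = 0.3
    seed: int = 0


@dataclass
class FeatureSelectionResult:
    """Nested selection output: prediction <= interpretation <= thresholded."""

    ranked_features: list[str]
    importance_mean: np.ndarray
    importance_sd: np.ndarray
    thresholded_set: list[str]
    interpretation_set: list[str]
    prediction_set: list[str]
    oob_trajectory: list[float] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "ranked_features": self.ranked_features,
            "importance_mean": [float(v) for v in self.importance_mean],
            "importance_sd": [float(v) for v in self.importance_sd],
            "thresholded_set": self.thresholded_set,
            "interpretation_set": self.interpretation_set,
            "prediction_set": self.prediction_set,
            "oob_trajectory": [float(v) for v in self.oob_trajectory],
            "seed": self.seed,
        }


def _forest(config: SelectionConfig, seed: int, oob: bool = False) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features="sqrt",
        oob_score=oob,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def rank_importances(
    features: np.ndarray,
    labels: np.ndarray,
    names: list[str] | None = None,
    n_forests: int | None = None,
    config: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Permutation importances averaged over independent forests.

    Returns a DataFrame (name, mean, sd) sorted by descending mean importance,
    ties broken by name.
    """
    if config is None:
        config = SelectionConfig()
    if n_forests is None:
        n_forests = config.n_forests_ranking
    if n_forests < 1:
        raise ValueError("n_forests must be >= 1")
    X = np.asarray(features)
    y = np.asarray(labels)
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    imps = np.empty((n_forests, X.shape[1]))
    for k in range(n_forests):
        seed = config.seed * 100003 + k
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=config.holdout_frac, random_state=seed, stratify=y
        )
        est = _forest(config, seed).fit(Xtr, ytr)
        res = permutation_importance(
            est, Xte, yte, n_repeats=1, random_state=seed, n_jobs=1
        )
        imps[k] = res.importances_mean
    df = pd.DataFrame(
        {"name": names, "mean": imps.mean(axis=0), "sd": imps.std(axis=0, ddof=1)}
    )
    return df.sort_values(
        ["mean", "name"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def threshold_step(ranked: pd.DataFrame) -> list[str]:
    """Retain features whose mean importance exceeds the noise threshold.

    The threshold is the minimum of a piecewise-constant (regression tree)
    fit of importance sd versus rank: the flat low-sd tail of the ranking is
    where pure-noise features live, and its predicted sd bounds their
    importance scale.
    """
    sds = ranked["sd"].to_numpy()
    means = ranked["mean"].to_numpy()
    if len(ranked) == 1:
        return list(ranked["name"])
    ranks = np.arange(len(ranked), dtype=np.float64).reshape(-1, 1)
    tree = DecisionTreeRegressor(
        max_leaf_nodes=max(2, len(ranked) // 10 + 1), random_state=0
    ).fit(ranks, sds)
    threshold = float(tree.predict(ranks).min())
    keep = means > threshold
    return list(ranked["name"][keep])


def _oob_error(X: np.ndarray, y: np.ndarray, config: SelectionConfig, seed: int) -> float:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sparse-OOB warnings on tiny forests
        est = _forest(config, seed, oob=True).fit(X, y)
    return 1.0 - float(est.oob_score_)


def interpretation_step(
    thresholded_set: list[str],
    features: np.ndarray,
    labels: np.ndarray,
    names: list[str],
    config: SelectionConfig | None = None,
) -> tuple[list[str], list[float]]:
    """Smallest ranked prefix whose OOB error is within 1 sd of the minimum.

    Returns the interpretation set and the OOB error trajectory over nested
    prefixes.
    """
    if config is None:
        config = SelectionConfig()
    if not thresholded_set:
        raise ValueError("empty thresholded set")
    X = np.asarray(features)
    y = np.asarray(labels)
    col = {n: i for i, n in enumerate(names)}
    idx = [col[n] for n in thresholded_set]
    errors = [
        _oob_error(X[:, idx[: k + 1]], y, config, config.seed * 7919 + k)
        for k in range(len(idx))
    ]
    k_min = int(np.argmin(errors))
    reps = [
        _oob_error(X[:, idx[: k_min + 1]], y, config, config.seed * 104729 + 500 + r)
        for r in range(config.n_forests_trajectory)
    ]
    sd = float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0
    cut = min(errors) + sd
    k_keep = next(k for k, e in enumerate(errors) if e <= cut)
    return thresholded_set[: k_keep + 1], errors


def prediction_step(
    interpretation_set: list[str],
    features: np.ndarray,
    labels: np.ndarray,
    names: list[str],
    config: SelectionConfig | None = None,
    oob_trajectory: list[float] | None = None,
) -> list[str]:
    """Greedy forward selection in interpretation order.

    A feature is added only if it lowers OOB error by more than the mean OOB
    fluctuation estimated from the flat tail of the interpretation trajectory
    (or from replicate forests when no tail is available).
    """
    if config is None:
        config = SelectionConfig()
    if not interpretation_set:
        raise ValueError("empty interpretation set")
    if len(interpretation_set) == 1:
        return list(interpretation_set)
    X = np.asarray(features)
    y = np.asarray(labels)
    col = {n: i for i, n in enumerate(names)}
    if oob_trajectory is not None and len(oob_trajectory) > len(interpretation_set) + 1:
        tail = np.asarray(oob_trajectory[len(interpretation_set):])
        fluct = float(np.mean(np.abs(np.diff(tail)))) if len(tail) > 1 else 0.0
    else:
        reps = [
            _oob_error(
                X[:, [col[n] for n in interpretation_set]], y, config,
                config.seed * 15485863 + 900 + r,
            )
            for r in range(config.n_forests_trajectory)
        ]
        fluct = float(np.mean(np.abs(np.diff(reps))))
    def _mean_oob(feature_names: list[str], tag: int) -> float:
        # averaged over two replicate forests so a candidate's chance
        # fluctuation cannot mimic a real error drop
        idx = [col[n] for n in feature_names]
        return float(np.mean([
            _oob_error(X[:, idx], y, config, config.seed * 31 + 2 * tag + r)
            for r in range(2)
        ]))

    selected = [interpretation_set[0]]
    e_cur = _mean_oob(selected, 0)
    for j, name in enumerate(interpretation_set[1:], start=1):
        cand = selected + [name]
        e_new = _mean_oob(cand, j)
        if e_cur - e_new > fluct:
            selected = cand
            e_cur = e_new
    return selected


def select_features(
    features: np.ndarray,
    labels: np.ndarray,
    names: list[str] | None = None,
    config: SelectionConfig | None = None,
) -> FeatureSelectionResult:
    """Run the full two-step procedure; sets are nested by construction."""
    if config is None:
        config = SelectionConfig()
    X = np.asarray(features)
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    ranked = rank_importances(X, labels, names, config=config)
    thresholded = threshold_step(ranked)
    if not thresholded:
        return FeatureSelectionResult(
            ranked_features=list(ranked["name"]),
            importance_mean=ranked["mean"].to_numpy(),
            importance_sd=ranked["sd"].to_numpy(),
            thresholded_set=[], interpretation_set=[], prediction_set=[],
            seed=config.seed,
        )
    interp, trajectory = interpretation_step(thresholded, X, labels, names, config)
    pred = prediction_step(interp, X, labels, names, config, trajectory)
    return FeatureSelectionResult(
        ranked_features=list(ranked["name"]),
        importance_mean=ranked["mean"].to_numpy(),
        importance_sd=ranked["sd"].to_numpy(),
        thresholded_set=list(thresholded),
        interpretation_set=list(interp),
        prediction_set=list(pred),
        oob_trajectory=trajectory,
        seed=config.seed,
    )
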