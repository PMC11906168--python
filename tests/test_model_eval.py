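import numpy as np
import pandas as pd
import pytest

from steppemap.model_eval import (
    ConfusionMatrix,
    DescriptorStack,
    HabitatClassificationModel,
    RFConfig,
    build_cv_units,
    compare_models,
    compute_metrics,
    cross_validate,
    fuse_time_series,
    kappa_variance,
    round_half_up,
    train_rf,
)
from steppemap.sampling import GroundTruthSet


def _random_cm(rng, scale=200):
    counts = rng.integers(0, scale, (4, 4))
    counts[np.diag_indices(4)] += scale
    return ConfusionMatrix(counts)


def _toy_gt(n_plots=6, per_plot=8, n_points=20, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_plots):
        for k in range(per_plot):
            rows.append((p * 50 + k, 10, "C0", f"P{p}", "plot_circle"))
    for cls, src in [("C1", "point"), ("C2", "transect"), ("C3", "point")]:
        for k in range(n_points):
            rows.append((int(rng.integers(0, 1000)), int(rng.integers(100, 999)),
                         cls, f"{cls}_{k}", src))
    df = pd.DataFrame(rows, columns=["row", "col", "class", "unit", "source"])
    return GroundTruthSet(df.drop_duplicates(["row", "col", "class"]))


def _separable_features(gt, rng, noise=0.05):
    classes = sorted(gt.samples["class"].unique())
    centers = {c: 10.0 * i for i, c in enumerate(classes)}
    base = gt.samples["class"].map(centers).to_numpy()[:, None]
    return base + noise * rng.standard_normal((len(gt), 3))


class TestFusion:
    def test_six_dates_by_74_features_gives_444(self):
        stacks = [
            DescriptorStack(np.zeros((5, 74)), [f"f{i}" for i in range(74)], f"d{t}")
            for t in range(6)
        ]
        fused = fuse_time_series(stacks)
        assert fused.D == 444
        assert fused.names[0] == "d0_f0" and fused.names[-1] == "d5_f73"

    def test_six_dates_texture_only_gives_324(self):
        stacks = [
            DescriptorStack(np.zeros((3, 54)), [f"g{i}" for i in range(54)], f"d{t}")
            for t in range(6)
        ]
        assert fuse_time_series(stacks).D == 324

    def test_single_date_is_identity(self):
        s = DescriptorStack(np.arange(6.0).reshape(2, 3), ["a", "b", "c"], "d0")
        fused = fuse_time_series([s])
        assert fused.D == 3
        np.testing.assert_array_equal(fused.values, s.values)

    def test_inconsistent_layer_sets_are_an_error(self):
        a = DescriptorStack(np.zeros((2, 2)), ["a", "b"], "d0")
        b = DescriptorStack(np.zeros((2, 2)), ["a", "c"], "d1")
        with pytest.raises(ValueError, match="inconsistent"):
            fuse_time_series([a, b])


class TestMetrics:
    def test_diagonal_matrix_is_perfect(self):
        m = compute_metrics(ConfusionMatrix(np.diag([50, 30, 20, 10])))
        assert m.oa == pytest.approx(100.0)
        assert m.kappa == pytest.approx(1.0)
        assert np.allclose(m.pa, 1.0) and np.allclose(m.ua, 1.0)

    def test_identities_hold_two_ways(self, rng):
        for _ in range(10):
            cm = _random_cm(rng)
            m = compute_metrics(cm)
            n = cm.n
            counts = cm.counts
            assert m.oa == pytest.approx(100 * np.trace(counts) / n, abs=1e-12)
            p_o = np.trace(counts) / n
            p_e = (cm.row_sums @ cm.col_sums) / n**2
            assert m.kappa == pytest.approx((p_o - p_e) / (1 - p_e), abs=1e-12)
            for i in range(4):
                assert m.pa[i] == pytest.approx(counts[i, i] / cm.row_sums[i], abs=1e-12)
                assert m.ua[i] == pytest.approx(counts[i, i] / cm.col_sums[i], abs=1e-12)
                assert m.f[i] == pytest.approx(
                    2 * m.pa[i] * m.ua[i] / (m.pa[i] + m.ua[i]), abs=1e-12
                )
            np.testing.assert_array_equal(cm.fn, cm.row_sums - np.diag(counts))
            np.testing.assert_array_equal(cm.fp, cm.col_sums - np.diag(counts))

    def test_kappa_invariant_to_joint_class_permutation(self, rng):
        cm = _random_cm(rng)
        perm = rng.permutation(4)
        cm2 = ConfusionMatrix(cm.counts[np.ix_(perm, perm)])
        assert compute_metrics(cm).kappa == pytest.approx(
            compute_metrics(cm2).kappa, abs=1e-12
        )
        assert kappa_variance(cm) == pytest.approx(kappa_variance(cm2), abs=1e-15)

    def test_round_half_up(self):
        assert round_half_up(0.865, 2) == 0.87
        assert round_half_up(0.864999, 2) == 0.86

    def test_empty_matrix_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            compute_metrics(ConfusionMatrix(np.zeros((4, 4), dtype=int)))


class TestCompareModels:
    def test_matrix_vs_itself_not_significant(self, rng):
        cm = _random_cm(rng)
        verdict = compare_models(cm, cm)
        assert verdict["z"] == 0.0 and not verdict["significant"]

    def test_perfect_vs_chance_is_significant(self, rng):
        n = 8743
        perfect = ConfusionMatrix(np.diag([8456, 123, 134, 30]))
        # random assignment proportional to marginals
        rows = np.array([8456, 123, 134, 30])
        chance = ConfusionMatrix(
            np.round(np.outer(rows, rows) / n).astype(int)
        )
        verdict = compare_models(perfect, chance)
        assert verdict["significant"] and abs(verdict["z"]) > 10


class TestCVUnits:
    def test_21_plots_plus_three_classes_give_36_units(self):
        gt = _toy_gt(n_plots=21, per_plot=5, n_points=25, seed=3)
        units = build_cv_units(gt, seed=0)
        assert len(units) == 21 + 3 * 5

    def test_units_cover_every_sample_exactly_once(self):
        gt = _toy_gt()
        units = build_cv_units(gt, seed=1)
        idx = np.concatenate(units)
        assert len(idx) == len(gt)
        assert len(np.unique(idx)) == len(gt)

    def test_same_seed_gives_identical_partitions(self):
        gt = _toy_gt()
        a = build_cv_units(gt, seed=5)
        b = build_cv_units(gt, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestRandomForest:
    def test_separable_training_votes(self, rng):
        gt = _toy_gt()
        X = _separable_features(gt, rng)
        est = train_rf(X, gt.samples["class"].to_numpy(), RFConfig(n_trees=50, seed=0))
        proba = est.predict_proba(X)
        assert proba.max(axis=1).min() == pytest.approx(1.0)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="single-class"):
            train_rf(np.zeros((10, 2)), np.array(["C0"] * 10), RFConfig(n_trees=5))

    def test_fixed_seed_determinism(self, rng):
        gt = _toy_gt()
        X = _separable_features(gt, rng, noise=3.0)
        y = gt.samples["class"].to_numpy()
        p1 = train_rf(X, y, RFConfig(n_trees=30, seed=9)).predict(X)
        p2 = train_rf(X, y, RFConfig(n_trees=30, seed=9)).predict(X)
        assert (p1 == p2).all()

    def test_label_permutation_drops_to_majority_rate(self, rng):
        gt = _toy_gt(n_plots=10, per_plot=10, n_points=30, seed=2)
        X = rng.standard_normal((len(gt), 5))  # label-independent features
        y = gt.samples["class"].to_numpy()
        est = train_rf(X, y, RFConfig(n_trees=100, seed=0))
        est_oob = est.__class__(
            n_estimators=100, oob_score=True, random_state=0
        ).fit(X, y)
        majority = max(np.bincount(pd.factorize(y)[0])) / len(y)
        assert est_oob.oob_score_ <= majority + 0.1


class TestCrossValidate:
    def test_separable_features_give_diagonal_matrix(self, rng):
        gt = _toy_gt()
        X = _separable_features(gt, rng)
        cm = cross_validate(X, gt, RFConfig(n_trees=30, seed=0), seed=0)
        assert np.trace(cm.counts) == cm.n == len(gt)

    def test_model_results_surface(self, rng):
        gt = _toy_gt()
        X = _separable_features(gt, rng)
        model = HabitatClassificationModel(X, gt, ["a", "b", "c"],
                                           RFConfig(n_trees=30, seed=0))
        res = model.fit(seed=0)
        assert res.metrics.oa == pytest.approx(100.0)
        assert "kappa" in res.summary()
        assert res.confusion_frame().to_numpy().sum() == len(gt)
        sub = model.subset(["a"])
        assert sub.features.shape == (len(gt), 1)
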