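import numpy as np
import pytest
from shapely.geometry import Polygon, box

from steppemap.features import compute_descriptors_at, family_feature_names
from steppemap.imagery import CLASS_CODES, GeoTransform
from steppemap.mapping import (
    HabitatMap,
    apply_confidence_mask,
    classify_raster,
    zone_extent_stats,
)
from steppemap.model_eval import RFConfig, train_rf
from steppemap.sampling import assemble_ground_truth

from oracles import point_in_polygon


@pytest.fixture(scope="module")
def spectral_model(tiny_scene_module):
    cfg, series, geometry, labels = tiny_scene_module
    gt = assemble_ground_truth(geometry, series, radius_m=0.2,
                               transect_count=cfg.transect_count)
    stack = compute_descriptors_at(series, gt.pixels, families=("spectral",))
    est = train_rf(stack.values, gt.samples["class"].to_numpy(),
                   RFConfig(n_trees=60, seed=0))
    return series, est, stack.names, labels


@pytest.fixture(scope="module")
def tiny_scene_module():
    from steppemap.synthetic import SceneConfig, generate_scene_series

    cfg = SceneConfig(
        height=96, width=96, gsd=0.08, n_plots=3, n_shrub_points=12,
        n_bare_points=6, transect_count=18, n_shrub_blobs=2, n_bare_patches=2,
        shrub_radius_px=(10, 16), bare_radius_px=(6, 10), min_spacing_m=1.0,
        seed=3,
    )
    return (cfg, *generate_scene_series(cfg))


class TestClassifyRaster:
    def test_tile_size_invariance_is_bit_exact(self, spectral_model):
        series, est, names, _ = spectral_model
        a = classify_raster(series, est, names, tile_size=96)
        b = classify_raster(series, est, names, tile_size=37)
        np.testing.assert_array_equal(a.label_idx, b.label_idx)
        np.testing.assert_array_equal(a.confidence, b.confidence)

    def test_interior_accuracy_against_true_labels(self, spectral_model):
        series, est, names, labels = spectral_model
        hmap = classify_raster(series, est, names, tile_size=96)
        interior = np.zeros_like(labels, dtype=bool)
        interior[8:-8, 8:-8] = True
        confident = ~hmap.low_confidence_mask & interior
        agree = (hmap.label_idx == labels) & confident
        assert agree.sum() / confident.sum() >= 0.9

    def test_unknown_feature_spec_is_an_error(self, spectral_model):
        series, est, names, _ = spectral_model
        with pytest.raises(ValueError, match="unavailable date"):
            classify_raster(series, est, ["2030-01-01_R"], tile_size=96)


class TestConfidenceMask:
    def _map(self):
        conf = np.array([[0.55, 0.8], [1.0, 0.25]])
        return HabitatMap(np.zeros((2, 2), dtype=np.uint8), conf,
                          GeoTransform(0, 2, 1.0), 0.6)

    def test_threshold_zero_empty_mask(self):
        assert not apply_confidence_mask(self._map(), 0.0).low_confidence_mask.any()

    def test_threshold_one_masks_non_unanimous(self):
        m = apply_confidence_mask(self._map(), 1.0)
        np.testing.assert_array_equal(
            m.low_confidence_mask, np.array([[True, True], [False, True]])
        )

    def test_vote_example_masked_at_0p6(self):
        # votes (0.55, 0.25, 0.15, 0.05): winner 0.55 < 0.6 -> masked
        m = self._map()
        assert m.low_confidence_mask[0, 0]
        assert not m.low_confidence_mask[0, 1]

    def test_labels_preserved_and_threshold_validated(self):
        m = self._map()
        m2 = apply_confidence_mask(m, 0.9)
        np.testing.assert_array_equal(m.label_idx, m2.label_idx)
        with pytest.raises(ValueError):
            apply_confidence_mask(m, 1.5)


class TestZoneStats:
    def _toy_map(self):
        lab = np.zeros((20, 20), dtype=np.uint8)
        lab[:, 10:] = 1  # half A / half B
        conf = np.ones((20, 20))
        return HabitatMap(lab, conf, GeoTransform(0.0, 20.0, 1.0), 0.6)

    def test_half_and_half_zone(self):
        report = zone_extent_stats(self._toy_map(), [(box(0, 0, 20, 20), "Z")])
        row = report.table.iloc[0]
        assert row["pct_C0"] == pytest.approx(50.0)
        assert row["pct_C1"] == pytest.approx(50.0)
        assert row["pct_low_confidence"] == 0.0

    def test_fully_masked_zone(self):
        m = self._toy_map()
        m = HabitatMap(m.label_idx, np.zeros((20, 20)), m.geotransform, 0.6)
        report = zone_extent_stats(m, [(box(0, 0, 20, 20), "Z")])
        assert report.table.iloc[0]["pct_low_confidence"] == pytest.approx(100.0)

    def test_triangle_zone_matches_enumeration_oracle(self):
        m = self._toy_map()
        verts = [(1.0, 1.0), (18.0, 2.0), (9.0, 17.0)]
        report = zone_extent_stats(m, [(Polygon(verts), "T")])
        inside = [
            (r, c)
            for r in range(20)
            for c in range(20)
            if point_in_polygon(c + 0.5, 20.0 - (r + 0.5), verts)
        ]
        n = len(inside)
        want_c1 = 100.0 * sum(1 for r, c in inside if c >= 10) / n
        row = report.table.iloc[0]
        assert row["n_pixels"] == n
        assert row["pct_C1"] == pytest.approx(want_c1)
        assert row["pct_C0"] + row["pct_C1"] == pytest.approx(100.0)

    def test_percentages_are_permutation_equivariant(self):
        m = self._toy_map()
        swapped = HabitatMap(1 - m.label_idx, m.confidence, m.geotransform, 0.6)
        a = zone_extent_stats(m, [(box(0, 0, 20, 20), "Z")]).table.iloc[0]
        b = zone_extent_stats(swapped, [(box(0, 0, 20, 20), "Z")]).table.iloc[0]
        assert a["pct_C0"] == pytest.approx(b["pct_C1"])

    def test_zone_without_pixels_is_an_error(self):
        with pytest.raises(ValueError, match="no pixel"):
            zone_extent_stats(self._toy_map(), [(box(100, 100, 101, 101), "far")])
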