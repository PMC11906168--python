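import numpy as np
import pytest
from shapely.geometry import LineString

from steppemap.imagery import GeometrySet, GeoTransform
from steppemap.sampling import (
    assemble_ground_truth,
    sample_plot_circle,
    sample_points,
    sample_transect,
)

from oracles import brute_force_circle_pixels

GT = GeoTransform(0.0, 4.0, 0.04)  # 100 x 100 px footprint, 4 m square
SHAPE = (100, 100)


class TestPlotCircle:
    def test_tiny_radius_on_pixel_center_gives_one_pixel(self):
        x, y = GT.pixel_to_world(50, 50)
        df = sample_plot_circle((float(x), float(y)), 0.01, GT, SHAPE)
        assert len(df) == 1
        assert (df.iloc[0]["row"], df.iloc[0]["col"]) == (50, 50)

    def test_one_meter_plot_fits_25x25_pixel_square(self):
        # the inscribed circle of a 1 m x 1 m plot at 4 cm GSD spans <= 25 px
        x, y = GT.pixel_to_world(50, 50)
        df = sample_plot_circle((float(x), float(y)), 0.5, GT, SHAPE)
        assert df["row"].max() - df["row"].min() + 1 == 25
        assert df["col"].max() - df["col"].min() + 1 == 25

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(5):
            cx = rng.uniform(0.8, 3.2)
            cy = rng.uniform(0.8, 3.2)
            df = sample_plot_circle((cx, cy), 0.5, GT, SHAPE)
            got = set(zip(df["row"], df["col"]))
            want = brute_force_circle_pixels((cx, cy), 0.5, 0.0, 4.0, 0.04, SHAPE)
            assert got == want

    def test_circle_outside_footprint_is_an_error(self):
        with pytest.raises(ValueError, match="outside"):
            sample_plot_circle((0.1, 0.1), 0.5, GT, SHAPE)

    def test_rotation_invariance(self):
        # circle sampling depends only on center and radius, never orientation
        df1 = sample_plot_circle((2.0, 2.0), 0.5, GT, SHAPE)
        df2 = sample_plot_circle((2.0, 2.0), 0.5, GT, SHAPE)
        assert df1.equals(df2)


class TestPoints:
    def test_one_sample_per_point_and_dedup(self):
        pts = [(2.0, 2.0, "C3", "a"), (2.0, 2.0, "C3", "b"), (1.0, 1.0, "C3", "c")]
        df = sample_points(pts, GT, SHAPE)
        assert len(df) == 2

    def test_thirty_points_give_thirty_samples(self, rng):
        pts = []
        seen = set()
        while len(pts) < 30:
            r, c = rng.integers(0, 100, 2)
            if (r, c) not in seen:
                seen.add((r, c))
                x, y = GT.pixel_to_world(int(r), int(c))
                pts.append((float(x), float(y), "C3", f"b{len(pts)}"))
        assert len(sample_points(pts, GT, SHAPE)) == 30

    def test_boundary_point_ties_to_smaller_index(self):
        # point exactly on the boundary between pixel centers (0,0) and (0,1)
        x_boundary = 0.04  # one full pixel east of origin corner
        df = sample_points([(x_boundary, 3.98, "C1", "p")], GT, SHAPE)
        assert (df.iloc[0]["row"], df.iloc[0]["col"]) == (0, 0)

    def test_point_outside_is_an_error(self):
        with pytest.raises(ValueError, match="outside"):
            sample_points([(99.0, 99.0, "C1", "p")], GT, SHAPE)


class TestTransect:
    def test_ten_meter_line_one_meter_spacing_gives_11_points(self):
        gt = GeoTransform(0.0, 20.0, 0.1)
        line = LineString([(1.0, 10.0), (11.0, 10.0)])
        df = sample_transect(line, gt, (200, 200), spacing_m=1.0)
        assert len(df) == 11

    def test_target_count_is_honored_and_equidistant(self):
        gt = GeoTransform(0.0, 20.0, 0.04)
        line = LineString([(1.0, 10.0), (8.0, 12.0), (15.0, 9.0)])
        df = sample_transect(line, gt, (500, 500), target_count=134)
        assert len(df) == 134

    def test_bent_polyline_matches_fine_resampling_oracle(self):
        gt = GeoTransform(0.0, 20.0, 0.01)
        line = LineString([(1.0, 10.0), (5.0, 13.0), (9.0, 10.0)])
        n = 21
        df = sample_transect(line, gt, (2000, 2000), target_count=n)
        # oracle: arc-length positions by dense numeric resampling
        dense = np.array([line.interpolate(d).coords[0]
                          for d in np.linspace(0, line.length, 20001)])
        seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        cum = np.concatenate([[0], np.cumsum(seg)])
        for k, target in enumerate(np.linspace(0, line.length, n)):
            x, y = dense[np.argmin(np.abs(cum - target))]
            row, col = gt.world_to_pixel(x, y)
            assert abs(df.iloc[k]["row"] - row) <= 1
            assert abs(df.iloc[k]["col"] - col) <= 1

    def test_zero_length_line_is_an_error(self):
        line = LineString([(1.0, 1.0), (1.0, 1.0)])
        with pytest.raises(ValueError, match="degenerate"):
            sample_transect(line, GT, SHAPE, target_count=5)


class TestAssemble:
    def test_scene_assembly_counts_and_units(self, tiny_scene):
        cfg, series, geometry, _ = tiny_scene
        gt = assemble_ground_truth(geometry, series, radius_m=0.2,
                                   transect_count=cfg.transect_count)
        counts = gt.class_counts
        assert set(counts) == {"C0", "C1", "C2", "C3"}
        assert counts["C2"] == cfg.transect_count
        assert counts["C3"] == cfg.n_bare_points
        plot_units = gt.samples[gt.samples["source"] == "plot_circle"]["unit"]
        assert plot_units.nunique() == cfg.n_plots
        # every C0 plot's samples share exactly one unit id
        per_plot = gt.samples[gt.samples["class"] == "C0"].groupby("unit").size()
        assert (per_plot > 1).all()

    def test_empty_geometry_is_an_error(self, tiny_scene):
        _, series, _, _ = tiny_scene
        with pytest.raises(ValueError, match="empty"):
            assemble_ground_truth(GeometrySet(), series)
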