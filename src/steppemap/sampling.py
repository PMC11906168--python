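"""Ground-truth sample extraction with CV grouping units.

Three sampling geometries mirror how field reference data is collected:

* steppe (C0) survey plots: every pixel whose center falls in the circle
  inscribed in the 1 m x 1 m plot (radius 0.5 m by default), one grouping
  unit per plot;
* shrub (C1) and bare-land (C3) GPS points: one pixel per point;
* the forest-steppe (C2) transect: points at equal arc length along the
  polyline, both endpoints included, then one pixel per point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .imagery import GeometrySet, GeoTransform, OrthomosaicSeries

SAMPLE_COLUMNS = ("row", "col", "class", "unit", "source")


@dataclass
class GroundTruthSet:
    """Labeled pixel samples with class, CV grouping unit and source kind."""

    samples: pd.DataFrame  # columns: row, col, class, unit, source

    def __post_init__(self) -> None:
        missing = set(SAMPLE_COLUMNS) - set(self.samples.columns)
        if missing:
            raise ValueError(f"missing sample columns: {sorted(missing)}")
        if self.samples["unit"].isna().any():
            raise ValueError("every sample needs a unit id")
        dup = self.samples.duplicated(subset=["row", "col", "class"])
        if dup.any():
            raise ValueError("duplicate (row, col, class) samples")

    @property
    def class_counts(self) -> dict[str, int]:
        return self.samples["class"].value_counts().to_dict()

    @property
    def pixels(self) -> np.ndarray:
        return self.samples[["row", "col"]].to_numpy(dtype=np.intp)

    def __len__(self) -> int:
        return len(self.samples)


def sample_plot_circle(
    center: tuple[float, float],
    radius_m: float,
    geotransform: GeoTransform,
    shape: tuple[int, int],
    class_code: str = "C0",
    unit_id: str = "plot0",
) -> pd.DataFrame:
    """All pixels whose centers lie within ``radius_m`` of a plot center."""
    cx, cy = center
    px = geotransform.pixel_size
    h, w = shape
    if not (
        geotransform.origin_x <= cx - radius_m
        and cx + radius_m <= geotransform.origin_x + w * px
        and geotransform.origin_y - h * px <= cy - radius_m
        and cy + radius_m <= geotransform.origin_y
    ):
        raise ValueError("circle outside raster footprint")
    r_c, c_c = geotransform.world_to_pixel(cx, cy)
    half = int(np.ceil(radius_m / px)) + 1
    rows = np.arange(max(0, r_c - half), min(h, r_c + half + 1))
    cols = np.arange(max(0, c_c - half), min(w, c_c + half + 1))
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    x, y = geotransform.pixel_to_world(rr, cc)
    inside = (x - cx) ** 2 + (y - cy) ** 2 <= radius_m**2
    return pd.DataFrame(
        {
            "row": rr[inside].astype(int),
            "col": cc[inside].astype(int),
            "class": class_code,
            "unit": unit_id,
            "source": "plot_circle",
        }
    )


def sample_points(
    points: list[tuple[float, float, str, str]],
    geotransform: GeoTransform,
    shape: tuple[int, int],
    source: str = "point",
) -> pd.DataFrame:
    """One labeled pixel per world point (nearest center; duplicates dropped)."""
    recs = []
    for x, y, cls, pid in points:
        row, col = geotransform.world_to_pixel(x, y)
        if not (0 <= row < shape[0] and 0 <= col < shape[1]):
            raise ValueError(f"point ({x}, {y}) outside raster footprint")
        recs.append((row, col, cls, str(pid), source))
    df = pd.DataFrame(recs, columns=list(SAMPLE_COLUMNS))
    return df.drop_duplicates(subset=["row", "col", "class"]).reset_index(drop=True)


def sample_transect(
    line: LineString,
    geotransform: GeoTransform,
    shape: tuple[int, int],
    spacing_m: float | None = None,
    target_count: int | None = None,
    class_code: str = "C2",
) -> pd.DataFrame:
    """Equidistant arc-length samples along a polyline, endpoints included.

    Either ``spacing_m`` or ``target_count`` must be given.  With
    ``spacing_m``, the point count is ``round(length / spacing) + 1`` and the
    spacing is adjusted so both endpoints are sampled exactly.
    """
    if (spacing_m is None) == (target_count is None):
        raise ValueError("give exactly one of spacing_m or target_count")
    length = line.length
    if target_count is not None:
        n = int(target_count)
    else:
        if spacing_m <= 0:
            raise ValueError("spacing must be positive")
        n = int(round(length / spacing_m)) + 1
    if n > 1 and length == 0:
        raise ValueError("degenerate zero-length transect")
    dists = np.linspace(0.0, length, n)
    pts = [
        (p.x, p.y, class_code, f"T{i}")
        for i, d in enumerate(dists)
        for p in [line.interpolate(d)]
    ]
    return sample_points(pts, geotransform, shape, source="transect")


def assemble_ground_truth(
    geometry: GeometrySet,
    series: OrthomosaicSeries,
    radius_m: float = 0.5,
    transect_count: int | None = None,
    transect_spacing_m: float | None = None,
) -> GroundTruthSet:
    """Build the full labeled sample table from the three sampling geometries.

    Plot centers are sampled by inscribed circle (one unit per plot), points
    by nearest pixel, the transect by equidistant arc-length sampling.  Every
    class present in the geometry must yield at least one sample.
    """
    if geometry.is_empty():
        raise ValueError("empty ground-truth geometry")
    gt = series.geotransform
    shape = series.shape
    parts: list[pd.DataFrame] = []
    for x, y, cls, pid in geometry.plot_centers:
        parts.append(
            sample_plot_circle((x, y), radius_m, gt, shape, cls, unit_id=str(pid))
        )
    if geometry.points:
        parts.append(sample_points(geometry.points, gt, shape))
    if geometry.transect is not None:
        line, cls = geometry.transect
        if transect_count is None and transect_spacing_m is None:
            transect_count = 134
        parts.append(
            sample_transect(
                line, gt, shape,
                spacing_m=transect_spacing_m,
                target_count=transect_count,
                class_code=cls,
            )
        )
    df = pd.concat(parts, ignore_index=True)
    df = df.drop_duplicates(subset=["row", "col", "class"]).reset_index(drop=True)
    if (df.groupby("class").size() == 0).any() or df.empty:
        raise ValueError("a class yielded zero samples")
    return GroundTruthSet(df)
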