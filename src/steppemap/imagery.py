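"""Core raster/vector data model and I/O for orthomosaic time series.

Rasters are plain multi-page/3-band TIFF files; georeferencing (affine
geotransform, CRS identifier, GSD) travels in a small JSON sidecar next to
each raster (``<name>.tif`` + ``<name>.tif.geo.json``).  Geometry is GeoJSON
with a ``class`` property, or CSV with x, y, class, id columns.

Conventions: pixel indices are 0-based ``(row, col)``; world coordinates of a
pixel refer to its *center*; the geotransform is north-up (y decreases with
increasing row).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from shapely.geometry import LineString, Point, Polygon, shape

#: Habitat class codes and display names, in fixed order.
CLASS_CODES = ("C0", "C1", "C2", "C3")
CLASS_NAMES = {
    "C0": "Steppe",
    "C1": "Shrubs",
    "C2": "Forest-steppe",
    "C3": "Bare/fallow land",
}


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine map between pixel indices and world coordinates.

    ``origin_x``/``origin_y`` are the world coordinates of the *outer corner*
    of pixel (0, 0); ``pixel_size`` is the ground sampling distance in
    world units (m) per pixel, identical in x and y.
    """

    origin_x: float
    origin_y: float
    pixel_size: float

    def pixel_to_world(self, row: int | np.ndarray, col: int | np.ndarray):
        """World coordinates of the center of pixel (row, col)."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.pixel_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.pixel_size
        return x, y

    def world_to_pixel(self, x: float, y: float) -> tuple[int, int]:
        """Nearest pixel-center index of a world point (ties -> smaller index)."""
        col = (x - self.origin_x) / self.pixel_size - 0.5
        row = (self.origin_y - y) / self.pixel_size - 0.5
        # round-half-down so a point on a pixel boundary maps to the smaller index
        return int(np.ceil(row - 0.5)), int(np.ceil(col - 0.5))

    def to_dict(self) -> dict:
        return {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "pixel_size": self.pixel_size,
        }


@dataclass
class OrthomosaicSeries:
    """T co-registered 3-band 8-bit orthomosaics with acquisition dates.

    Invariants (checked on construction): all rasters share shape and
    geotransform; dates strictly increasing; values in [0, 255].
    """

    dates: list[str]
    rasters: list[np.ndarray]  # each H x W x 3, uint8
    geotransform: GeoTransform
    gsd: float = 0.04
    crs_id: str = "local"

    def __post_init__(self) -> None:
        if len(self.rasters) == 0:
            raise ValueError("no input rasters")
        if len(self.dates) != len(self.rasters):
            raise ValueError("one date per raster required")
        shape0 = self.rasters[0].shape
        for r in self.rasters:
            if r.ndim != 3 or r.shape[2] != 3:
                raise ValueError("non-3-band input")
            if r.shape != shape0:
                raise ValueError("grid mismatch across dates")
        if list(self.dates) != sorted(set(self.dates)):
            raise ValueError("dates must be strictly increasing")

    @property
    def T(self) -> int:
        return len(self.dates)

    @property
    def shape(self) -> tuple[int, int]:
        return self.rasters[0].shape[:2]

    def contains_world(self, x: float, y: float) -> bool:
        h, w = self.shape
        px = self.geotransform.pixel_size
        return (
            self.geotransform.origin_x <= x <= self.geotransform.origin_x + w * px
            and self.geotransform.origin_y - h * px <= y <= self.geotransform.origin_y
        )


@dataclass
class GeometrySet:
    """Ground-truth geometry: plot centers, points, transect, zones.

    ``plot_centers``/``points``: lists of (x, y, class_code, id).
    ``transect``: (LineString, class_code).  ``zones``: list of
    (Polygon, zone_id).
    """

    plot_centers: list[tuple[float, float, str, str]] = field(default_factory=list)
    points: list[tuple[float, float, str, str]] = field(default_factory=list)
    transect: tuple[LineString, str] | None = None
    zones: list[tuple[Polygon, str]] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.plot_centers or self.points or self.transect)


# ---------------------------------------------------------------------------
# raster I/O


def write_raster(
    path: str | Path,
    array: np.ndarray,
    geotransform: GeoTransform,
    gsd: float | None = None,
    crs_id: str = "local",
    band_names: Sequence[str] | None = None,
) -> None:
    """Write a raster TIFF plus its JSON geo-sidecar."""
    path = Path(path)
    tifffile.imwrite(path, array)
    meta = {
        "geotransform": geotransform.to_dict(),
        "gsd": gsd if gsd is not None else geotransform.pixel_size,
        "crs_id": crs_id,
    }
    if band_names is not None:
        meta["band_names"] = list(band_names)
    Path(str(path) + ".geo.json").write_text(json.dumps(meta, indent=1))


def read_raster(path: str | Path) -> tuple[np.ndarray, GeoTransform, dict]:
    """Read a raster TIFF and its geo-sidecar (if present)."""
    path = Path(path)
    array = tifffile.imread(path)
    sidecar = Path(str(path) + ".geo.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        gt = GeoTransform(**meta["geotransform"])
    else:
        meta = {"gsd": 1.0, "crs_id": "local"}
        gt = GeoTransform(0.0, float(array.shape[0]), 1.0)
    return array, gt, meta


def load_series(
    paths: Sequence[str | Path], dates: Sequence[str]
) -> OrthomosaicSeries:
    """Load co-registered 3-band rasters into an :class:`OrthomosaicSeries`.

    Mismatched grids are an error; no resampling is performed.
    """
    if len(paths) == 0:
        raise ValueError("no input rasters")
    if len(paths) != len(dates):
        raise ValueError("one date per path required")
    rasters, gts, metas = [], [], []
    for p in paths:
        a, gt, meta = read_raster(p)
        if a.ndim != 3 or a.shape[2] != 3:
            raise ValueError(f"non-3-band input: {p}")
        rasters.append(a)
        gts.append(gt)
        metas.append(meta)
    if any(g != gts[0] for g in gts):
        raise ValueError("geotransform mismatch across dates")
    order = np.argsort(np.asarray(dates, dtype=object))
    return OrthomosaicSeries(
        dates=[str(dates[i]) for i in order],
        rasters=[rasters[i] for i in order],
        geotransform=gts[0],
        gsd=float(metas[0].get("gsd", gts[0].pixel_size)),
        crs_id=str(metas[0].get("crs_id", "local")),
    )


def to_grayscale(rgb_raster: np.ndarray) -> np.ndarray:
    """Channel-neutral grayscale g = (R+G+B)/3, float in [0, 255]."""
    rgb_raster = np.asarray(rgb_raster)
    if rgb_raster.ndim != 3 or rgb_raster.shape[2] != 3:
        raise ValueError("expected an H x W x 3 raster")
    return rgb_raster.astype(np.float64).mean(axis=2)


def world_to_pixel(
    geotransform: GeoTransform,
    point: tuple[float, float],
    shape: tuple[int, int] | None = None,
) -> tuple[int, int]:
    """Nearest pixel-center (row, col) for a world point.

    If ``shape`` is given, points outside the raster footprint raise.
    """
    row, col = geotransform.world_to_pixel(*point)
    if shape is not None:
        h, w = shape
        if not (0 <= row < h and 0 <= col < w):
            raise ValueError(f"point {point} outside raster footprint")
    return row, col


# ---------------------------------------------------------------------------
# geometry I/O


def read_geometry(path: str | Path) -> GeometrySet:
    """Read ground-truth geometry from GeoJSON (``class`` / ``id`` / ``kind``
    properties) or CSV (x, y, class, id columns; points only)."""
    path = Path(path)
    gs = GeometrySet()
    if path.suffix.lower() == ".csv":
        with open(path) as f:
            for rec in csv.DictReader(f):
                gs.points.append(
                    (float(rec["x"]), float(rec["y"]), rec["class"], rec["id"])
                )
        return gs
    data = json.loads(path.read_text())
    for feat in data.get("features", []):
        geom = shape(feat["geometry"])
        props = feat.get("properties", {}) or {}
        cls = props.get("class", "")
        fid = str(props.get("id", len(gs.points) + len(gs.plot_centers)))
        kind = props.get("kind", "")
        if isinstance(geom, Point):
            rec = (geom.x, geom.y, cls, fid)
            if kind == "plot_center":
                gs.plot_centers.append(rec)
            else:
                gs.points.append(rec)
        elif isinstance(geom, LineString):
            gs.transect = (geom, cls)
        elif isinstance(geom, Polygon):
            gs.zones.append((geom, fid))
    return gs


def write_geometry(path: str | Path, gs: GeometrySet) -> None:
    """Write a GeometrySet as GeoJSON."""
    feats = []
    for x, y, cls, fid in gs.plot_centers:
        feats.append(_feat(Point(x, y), {"class": cls, "id": fid, "kind": "plot_center"}))
    for x, y, cls, fid in gs.points:
        feats.append(_feat(Point(x, y), {"class": cls, "id": fid, "kind": "point"}))
    if gs.transect is not None:
        line, cls = gs.transect
        feats.append(_feat(line, {"class": cls, "kind": "transect"}))
    for poly, zid in gs.zones:
        feats.append(_feat(poly, {"id": zid, "kind": "zone"}))
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats})
    )


def _feat(geom, props: dict) -> dict:
    return {
        "type": "Feature",
        "geometry": json.loads(json.dumps(geom.__geo_interface__)),
        "properties": props,
    }
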