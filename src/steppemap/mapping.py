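"""Dense whole-raster inference, confidence masking, and zone extent stats.

Inference is tiled and streaming: for each tile only the descriptor features
the deployed model actually uses are computed, directly from the orthomosaic
series.  All descriptors are functions of the global rasters and the pixel
location (texture windows read from the reflect-padded full raster,
morphological reconstruction is precomputed whole-image), so the result is
bit-identical for any tile size.

The per-pixel decision confidence is the fraction of ensemble votes for the
winning class; pixels below the confidence threshold (0.6 by default) form
the low-confidence mask, which is a view on the map -- labels are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .features import compute_spec_features_at, parse_feature_spec
from .imagery import CLASS_CODES, GeoTransform, OrthomosaicSeries, to_grayscale
from .morphology import MorphologyConfig, compute_morphological_features
from .texture import TextureConfig


@dataclass
class HabitatMap:
    """Per-pixel class labels + decision confidence + low-confidence mask."""

    label_idx: np.ndarray  # (H, W) index into class_codes
    confidence: np.ndarray  # (H, W) winning vote fraction in [0, 1]
    geotransform: GeoTransform
    threshold: float = 0.6
    class_codes: tuple[str, ...] = CLASS_CODES

    @property
    def low_confidence_mask(self) -> np.ndarray:
        return self.confidence < self.threshold

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(self.class_codes)[self.label_idx]


def classify_raster(
    series: OrthomosaicSeries,
    estimator,
    feature_spec: list[str],
    tile_size: int = 256,
    threshold: float = 0.6,
    texture_config: TextureConfig | None = None,
    morph_config: MorphologyConfig | None = None,
) -> HabitatMap:
    """Tiled dense inference with on-the-fly feature computation.

    ``feature_spec`` must list the fused feature names in the estimator's
    training column order (possibly a selected subset).  Label is the argmax
    vote fraction; confidence is the winning fraction.
    """
    texture_config = texture_config or TextureConfig()
    morph_config = morph_config or MorphologyConfig()
    by_date = parse_feature_spec(feature_spec, series.dates)  # validates spec
    h, w = series.shape
    # morphology is a whole-image operation: precompute once per needed date
    morph_caches: dict[str, np.ndarray] = {}
    for date, rgb in zip(series.dates, series.rasters):
        if "morphology" in by_date.get(date, {}):
            morph_caches[date] = compute_morphological_features(
                to_grayscale(rgb), morph_config
            )
    label_idx = np.zeros((h, w), dtype=np.uint8)
    confidence = np.zeros((h, w), dtype=np.float64)
    class_order = list(estimator.classes_)
    code_to_idx = np.array([CLASS_CODES.index(c) for c in class_order])
    for r0 in range(0, h, tile_size):
        for c0 in range(0, w, tile_size):
            r1, c1 = min(r0 + tile_size, h), min(c0 + tile_size, w)
            rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
            pixels = np.column_stack([rr.ravel(), cc.ravel()])
            X = compute_spec_features_at(
                series, pixels, feature_spec, texture_config, morph_config,
                morph_caches=morph_caches,
            )
            proba = estimator.predict_proba(X)
            win = np.argmax(proba, axis=1)
            label_idx[r0:r1, c0:c1] = code_to_idx[win].reshape(r1 - r0, c1 - c0)
            confidence[r0:r1, c0:c1] = proba[np.arange(len(win)), win].reshape(
                r1 - r0, c1 - c0
            )
    return HabitatMap(label_idx, confidence, series.geotransform, threshold)


def apply_confidence_mask(hmap: HabitatMap, threshold: float) -> HabitatMap:
    """Return the map with an updated confidence threshold (labels preserved)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return HabitatMap(
        hmap.label_idx, hmap.confidence, hmap.geotransform, threshold,
        hmap.class_codes,
    )


@dataclass
class ZoneReport:
    """Per-zone area and class-extent percentages."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def zone_extent_stats(
    hmap: HabitatMap, zones: list[tuple[Polygon, str]]
) -> ZoneReport:
    """Class percentages and low-confidence share per zone.

    Zone membership is by pixel-center point-in-polygon test (boundary counts
    as inside).  Class percentages are reported over *all* zone pixels
    (primary convention) and, additionally, over confident pixels only.
    """
    gt = hmap.geotransform
    h, w = hmap.label_idx.shape
    px = gt.pixel_size
    rows_out = []
    for poly, zid in zones:
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(0, int(np.floor((minx - gt.origin_x) / px - 0.5)))
        c1 = min(w - 1, int(np.ceil((maxx - gt.origin_x) / px - 0.5)))
        r0 = max(0, int(np.floor((gt.origin_y - maxy) / px - 0.5)))
        r1 = min(h - 1, int(np.ceil((gt.origin_y - miny) / px - 0.5)))
        rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
        x, y = gt.pixel_to_world(rr.ravel(), cc.ravel())
        inside = shapely.intersects_xy(poly, x, y)
        if not inside.any():
            raise ValueError(f"zone {zid} covers no pixel centers")
        rsel, csel = rr.ravel()[inside], cc.ravel()[inside]
        lab = hmap.label_idx[rsel, csel]
        low = hmap.low_confidence_mask[rsel, csel]
        n = len(lab)
        rec = {"zone": zid, "n_pixels": n, "area_ha": n * px * px / 10_000.0}
        for i, code in enumerate(hmap.class_codes):
            rec[f"pct_{code}"] = 100.0 * np.sum(lab == i) / n
        rec["pct_low_confidence"] = 100.0 * low.sum() / n
        n_conf = n - int(low.sum())
        for i, code in enumerate(hmap.class_codes):
            rec[f"pct_{code}_confident"] = (
                100.0 * np.sum((lab == i) & ~low) / n_conf if n_conf else np.nan
            )
        rows_out.append(rec)
    return ZoneReport(pd.DataFrame(rows_out))
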