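"""Synthetic multitemporal RGB scenes with the statistical structure the
habitat-mapping analysis assumes.

A scene is a zonal class layout (steppe matrix, a forest-steppe band, shrub
blobs, bare patches) rendered at each acquisition date as a per-class mean
RGB (the phenology palette) plus a class-specific correlated texture field
(Gaussian-filtered white noise, persistent across dates) plus per-date pixel
noise.  Palettes are built so that on every date at least one class pair is
color-confusable (steppe vs forest-steppe early in the season, steppe vs
bare land once the grass dries) while each pair separates on some other
date -- the property that makes time-series classifiers outperform any
single-date model.

Ground-truth geometry (survey-plot centers in the steppe, shrub and bare
GPS points, a transect polyline through the forest-steppe band, zone
polygons) and the true label raster are emitted alongside the image series.
Everything is a deterministic function of the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Polygon, box

from .imagery import CLASS_CODES, GeometrySet, GeoTransform, OrthomosaicSeries

DEFAULT_DATES = (
    "2021-04-16",
    "2021-05-21",
    "2021-06-08",
    "2021-06-28",
    "2021-08-04",
    "2021-09-30",
)


@dataclass(frozen=True)
class ClassAppearance:
    """Texture granularity and seasonal color trajectory of one class."""

    corr_length: float  # texture correlation length, px
    amplitude: float  # texture contrast amplitude, gray levels
    palette: tuple[tuple[float, float, float], ...]  # per-date mean RGB


def _default_appearance() -> dict[str, ClassAppearance]:
    # Steppe (C0): grass green in spring, straw-colored from August on.
    # Forest-steppe (C2) tracks C0 until late June (both are green canopies of
    # similar granularity), then stays green while the steppe dries.
    # Bare land (C3) is near-constant brown; the dried steppe converges on it
    # in August/September.  Shrubs (C1) are dark green with coarse texture.
    return {
        "C0": ClassAppearance(3.0, 18.0, (
            (105, 125, 70), (112, 132, 74), (120, 135, 78),
            (135, 132, 76), (150, 130, 80), (138, 122, 76),
        )),
        "C1": ClassAppearance(8.0, 26.0, (
            (70, 92, 55), (62, 95, 52), (56, 96, 50),
            (55, 92, 50), (60, 90, 54), (84, 86, 56),
        )),
        "C2": ClassAppearance(3.0, 18.0, (
            (105, 125, 70), (106, 128, 70), (114, 131, 74),
            (128, 128, 72), (86, 112, 62), (95, 105, 64),
        )),
        "C3": ClassAppearance(2.5, 16.0, (
            (150, 126, 95), (151, 127, 95), (152, 127, 96),
            (151, 126, 95), (150, 129, 82), (140, 123, 78),
        )),
    }


@dataclass
class SceneConfig:
    """Scene geometry, per-class appearance, GT layout and the master seed."""

    height: int = 1024
    width: int = 1024
    gsd: float = 0.04
    dates: tuple[str, ...] = DEFAULT_DATES
    appearance: dict[str, ClassAppearance] = field(default_factory=_default_appearance)
    noise_sd: float = 8.0
    # zonal layout
    forest_band_frac: float = 0.80  # rows below this fraction are forest-steppe
    n_shrub_blobs: int = 10
    shrub_radius_px: tuple[int, int] = (30, 60)
    n_bare_patches: int = 6
    bare_radius_px: tuple[int, int] = (15, 30)
    # ground-truth layout
    n_plots: int = 17
    plot_side_m: float = 1.0
    min_spacing_m: float = 5.0
    n_shrub_points: int = 123
    n_bare_points: int = 30
    transect_count: int = 134
    seed: int = 0

    def __post_init__(self) -> None:
        T = len(self.dates)
        for cls, app in self.appearance.items():
            if len(app.palette) != T:
                raise ValueError(f"palette of {cls} must have one entry per date")


def class_texture_field(
    corr_length: float, amplitude: float, shape: tuple[int, int], seed: int
) -> np.ndarray:
    """Correlated random gray field: low-pass filtered white noise.

    Standardized to zero mean and unit variance before scaling by
    ``amplitude``, so the amplitude is the field's marginal sd in gray levels.
    """
    if corr_length <= 0:
        raise ValueError("correlation length must be positive")
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("nonpositive field shape")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    if amplitude == 0:
        return np.zeros(shape)
    f = gaussian_filter(white, sigma=corr_length, mode="reflect")
    f = (f - f.mean()) / f.std()
    return amplitude * f


def phenology_palette(
    class_code: str, date_index: int, config: SceneConfig | None = None
) -> np.ndarray:
    """Mean RGB of one class at one acquisition date."""
    if config is None:
        config = SceneConfig()
    if class_code not in config.appearance:
        raise ValueError(f"unknown class {class_code}")
    if not 0 <= date_index < len(config.dates):
        raise ValueError("date index out of range")
    return np.asarray(config.appearance[class_code].palette[date_index], dtype=float)


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _build_labels(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = config.height, config.width
    labels = np.zeros((h, w), dtype=np.uint8)  # C0 matrix
    band_row = int(config.forest_band_frac * h)
    labels[band_row:, :] = 2  # forest-steppe band along the south
    # shrub blobs in the western part of the open grassland
    for _ in range(config.n_shrub_blobs):
        r = rng.integers(*config.shrub_radius_px)
        cy = rng.integers(int(0.05 * h) + r, int(0.72 * h) - r)
        cx = rng.integers(r + 2, int(0.40 * w) - r)
        labels[_disk_mask((h, w), (cy, cx), r)] = 1
    # bare/fallow patches near the eastern and northern edges
    for _ in range(config.n_bare_patches):
        r = rng.integers(*config.bare_radius_px)
        if rng.random() < 0.5:
            cy = rng.integers(r + 2, int(0.12 * h))
            cx = rng.integers(int(0.45 * w), w - r - 2)
        else:
            cy = rng.integers(int(0.15 * h), int(0.72 * h))
            cx = rng.integers(int(0.82 * w), w - r - 2)
        m = _disk_mask((h, w), (cy, cx), r) & (labels == 0)
        labels[m] = 3
    return labels


def _place_plots(
    labels: np.ndarray, config: SceneConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Plot centers (pixels) inside pure steppe, min-spacing constrained."""
    h, w = labels.shape
    gsd = config.gsd
    spacing_px = config.min_spacing_m / gsd
    clear_px = int(np.ceil(0.5 * config.plot_side_m * np.sqrt(2) / gsd)) + 3
    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < config.n_plots:
        attempts += 1
        if attempts > 20000:
            raise ValueError("plots not placeable under spacing constraint")
        r = int(rng.integers(clear_px, h - clear_px))
        c = int(rng.integers(clear_px, w - clear_px))
        patch = labels[r - clear_px : r + clear_px + 1, c - clear_px : c + clear_px + 1]
        if (patch != 0).any():
            continue
        if any((r - r0) ** 2 + (c - c0) ** 2 < spacing_px**2 for r0, c0 in centers):
            continue
        centers.append((r, c))
    return centers


def _sample_class_pixels(
    labels: np.ndarray, cls: int, n: int, rng: np.random.Generator, margin: int
) -> np.ndarray:
    """n distinct pixels of one class, at least ``margin`` px from other classes."""
    from scipy.ndimage import binary_erosion

    mask = labels == cls
    if margin > 0:
        mask = binary_erosion(mask, iterations=margin)
    rows, cols = np.nonzero(mask)
    if len(rows) < n:
        raise ValueError(f"class {cls} region too small for {n} points")
    pick = rng.choice(len(rows), size=n, replace=False)
    return np.column_stack([rows[pick], cols[pick]])


def generate_scene_series(
    config: SceneConfig | None = None,
) -> tuple[OrthomosaicSeries, GeometrySet, np.ndarray]:
    """Generate the image series, GT geometry, and the true label raster."""
    if config is None:
        config = SceneConfig()
    h, w = config.height, config.width
    root = np.random.SeedSequence(config.seed)
    rng_layout, rng_geom, rng_img = [
        np.random.default_rng(s) for s in root.spawn(3)
    ]
    labels = _build_labels(config, rng_layout)

    # persistent per-class texture fields
    field_seeds = root.spawn(4)
    fields = np.zeros((4, h, w))
    for ci, code in enumerate(CLASS_CODES):
        app = config.appearance[code]
        fields[ci] = class_texture_field(
            app.corr_length, app.amplitude, (h, w),
            int(field_seeds[ci].generate_state(1)[0] % (2**31)),
        )
    tex = np.take_along_axis(fields, labels[None].astype(np.intp), axis=0)[0]

    palettes = np.array(
        [config.appearance[c].palette for c in CLASS_CODES]
    )  # (4, T, 3)
    rasters = []
    for t in range(len(config.dates)):
        base = palettes[labels, t, :]  # (h, w, 3)
        img = base + tex[:, :, None] + rng_img.normal(0, config.noise_sd, (h, w, 3))
        rasters.append(np.clip(img, 0, 255).astype(np.uint8))

    gt = GeoTransform(origin_x=0.0, origin_y=h * config.gsd, pixel_size=config.gsd)
    series = OrthomosaicSeries(
        dates=list(config.dates), rasters=rasters, geotransform=gt, gsd=config.gsd
    )

    geometry = GeometrySet()
    for i, (r, c) in enumerate(_place_plots(labels, config, rng_geom)):
        x, y = gt.pixel_to_world(r, c)
        geometry.plot_centers.append((float(x), float(y), "C0", f"P{i:02d}"))
    for i, (r, c) in enumerate(
        _sample_class_pixels(labels, 1, config.n_shrub_points, rng_geom, 4)
    ):
        x, y = gt.pixel_to_world(r, c)
        geometry.points.append((float(x), float(y), "C1", f"S{i:03d}"))
    for i, (r, c) in enumerate(
        _sample_class_pixels(labels, 3, config.n_bare_points, rng_geom, 2)
    ):
        x, y = gt.pixel_to_world(r, c)
        geometry.points.append((float(x), float(y), "C3", f"B{i:02d}"))

    band_row = int(config.forest_band_frac * h)
    ty = lambda frac: (h - (band_row + frac * (h - band_row))) * config.gsd
    tx = lambda frac: frac * w * config.gsd
    geometry.transect = (
        LineString(
            [(tx(0.06), ty(0.45)), (tx(0.5), ty(0.30)), (tx(0.94), ty(0.60))]
        ),
        "C2",
    )

    def zone(r0, r1, c0, c1, zid) -> tuple[Polygon, str]:
        x0, x1 = c0 * w * config.gsd, c1 * w * config.gsd
        y0, y1 = (h - r1 * h) * config.gsd, (h - r0 * h) * config.gsd
        return box(x0, y0, x1, y1), zid

    geometry.zones = [
        zone(0.05, 0.42, 0.05, 0.42, "I"),
        zone(0.05, 0.42, 0.55, 0.94, "II"),
        zone(0.46, 0.74, 0.05, 0.44, "III"),
        zone(0.82, 0.98, 0.06, 0.94, "IV"),
        zone(0.46, 0.76, 0.52, 0.94, "V"),
    ]
    return series, geometry, labels


def planted_feature_benchmark(
    n: int,
    d_informative: int,
    d_noise: int,
    seed: int = 0,
    effect_size: float = 2.0,
    n_classes: int = 4,
    d_decoy: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Feature-selection test bed: class-dependent means + pure noise columns.

    Labels are uniform over ``n_classes``; each informative feature has
    class-specific means drawn at scale ``effect_size`` (in units of the unit
    observation noise); noise features are label-independent; optional decoys
    are noisy copies of informative features.
    """
    if n < 50:
        raise ValueError("n must be >= 50")
    if d_informative < 0 or d_noise < 0:
        raise ValueError("degenerate sizes")
    rng = np.random.default_rng(seed)
    y = rng.integers(0, n_classes, size=n)
    cols: dict[str, np.ndarray] = {}
    informative = [f"inf_{i}" for i in range(d_informative)]
    # class means on a centered grid with adjacent spacing = effect_size
    # (in units of the unit observation noise), randomly permuted per feature
    grid = effect_size * (np.arange(n_classes) - (n_classes - 1) / 2.0)
    mu = np.stack(
        [rng.permutation(grid) for _ in range(max(d_informative, 1))], axis=1
    )  # (n_classes, d_informative)
    for i, name in enumerate(informative):
        cols[name] = mu[y, i] + rng.standard_normal(n)
    for i in range(d_decoy):
        src = informative[i % max(d_informative, 1)]
        cols[f"decoy_{i}"] = cols[src] + rng.standard_normal(n)
    for i in range(d_noise):
        cols[f"noise_{i}"] = rng.standard_normal(n)
    X = pd.DataFrame(cols)
    labels = np.array([f"C{c}" for c in y])
    return X, labels, informative
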