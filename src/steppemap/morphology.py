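"""Morphological-profile (MP) descriptors: 11 features per pixel per date.

Openings and closings by reconstruction with a discrete disk ("ball")
structuring element of radius r = 1..5 form two 5-level profiles per image.
Opening by reconstruction removes bright structures narrower than the disk
without distorting what remains; closing by reconstruction is its dual on
dark structures.  The descriptor keeps only the profile *derivatives*
(absolute differences between successive levels, 4 per profile), one
"characteristic" per profile (the scale index of the dominant derivative),
and a single "classification" value (bright-dominated / dark-dominated /
flat) -- plain profile levels are not emitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, reconstruction

MORPH_FEATURE_NAMES = (
    "MPDerivOpening_scale1",
    "MPDerivOpening_scale2",
    "MPDerivOpening_scale3",
    "MPDerivOpening_scale4",
    "MPDerivClosing_scale1",
    "MPDerivClosing_scale2",
    "MPDerivClosing_scale3",
    "MPDerivClosing_scale4",
    "MPCharacteristicOpening",
    "MPCharacteristicClosing",
    "MPClassification",
)


@dataclass(frozen=True)
class MorphologyConfig:
    """(r, s, rs) = (5, 5, 1): five disk radii increasing from 1 in unit steps.

    ``flat_threshold`` is the minimum derivative magnitude (gray levels) for a
    pixel to be considered non-flat when computing the characteristic and
    classification features.
    """

    radii: tuple[int, ...] = (1, 2, 3, 4, 5)
    se_shape: str = "ball"
    flat_threshold: float = 1.0

    def __post_init__(self) -> None:
        if list(self.radii) != list(range(1, len(self.radii) + 1)):
            raise ValueError("radii must increase from 1 with unit step")
        if self.flat_threshold < 0:
            raise ValueError("flat_threshold must be nonnegative")


def _opening_by_reconstruction(img: np.ndarray, radius: int) -> np.ndarray:
    seed = ndimage.grey_erosion(img, footprint=disk(radius), mode="reflect")
    return reconstruction(seed, img, method="dilation")


def _closing_by_reconstruction(img: np.ndarray, radius: int) -> np.ndarray:
    seed = ndimage.grey_dilation(img, footprint=disk(radius), mode="reflect")
    return reconstruction(seed, img, method="erosion")


def reconstruction_profile(
    gray_raster: np.ndarray, config: MorphologyConfig | None = None
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Opening and closing by-reconstruction profiles at all configured radii.

    Returns ``(opening_levels, closing_levels)``, each a list of len(radii)
    images.  Opening levels are anti-extensive (<= input) and non-increasing
    in r; closing levels are extensive and non-decreasing.
    """
    if config is None:
        config = MorphologyConfig()
    gray_raster = np.asarray(gray_raster, dtype=np.float64)
    r_max = max(config.radii)
    if min(gray_raster.shape) < 2 * r_max + 1:
        raise ValueError("raster smaller than the largest structuring element")
    openings = [_opening_by_reconstruction(gray_raster, r) for r in config.radii]
    closings = [_closing_by_reconstruction(gray_raster, r) for r in config.radii]
    return openings, closings


def mp_derivatives(
    profiles: tuple[list[np.ndarray], list[np.ndarray]],
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Absolute differences between successive profile levels (4 per profile)."""
    openings, closings = profiles
    if len(openings) != 5 or len(closings) != 5:
        raise ValueError("expected 5-level profiles")
    d_open = [np.abs(openings[k] - openings[k + 1]) for k in range(4)]
    d_close = [np.abs(closings[k] - closings[k + 1]) for k in range(4)]
    return d_open, d_close


def mp_characteristic(
    deriv_maps: list[np.ndarray], flat_threshold: float = 1.0
) -> np.ndarray:
    """Scale index (1-4) of the maximal derivative; 0 where all are flat.

    Ties break toward the smallest qualifying scale.
    """
    stack = np.stack(deriv_maps, axis=0)
    char = np.argmax(stack, axis=0) + 1  # first max -> smallest scale
    flat = stack.max(axis=0) < flat_threshold
    char[flat] = 0
    return char.astype(np.float64)


def mp_classification(
    deriv_open: list[np.ndarray],
    deriv_close: list[np.ndarray],
    flat_threshold: float = 1.0,
) -> np.ndarray:
    """Per-pixel structure class: 1 bright-dominated, 2 dark-dominated, 0 flat."""
    max_o = np.stack(deriv_open, axis=0).max(axis=0)
    max_c = np.stack(deriv_close, axis=0).max(axis=0)
    out = np.zeros(max_o.shape, dtype=np.float64)
    out[(max_o > max_c) & (max_o >= flat_threshold)] = 1.0
    out[(max_c > max_o) & (max_c >= flat_threshold)] = 2.0
    return out


def compute_morphological_features(
    gray_raster: np.ndarray, config: MorphologyConfig | None = None
) -> np.ndarray:
    """The 11 MP feature layers (H, W, 11), ordered as MORPH_FEATURE_NAMES."""
    if config is None:
        config = MorphologyConfig()
    profiles = reconstruction_profile(gray_raster, config)
    d_open, d_close = mp_derivatives(profiles)
    layers = d_open + d_close
    layers.append(mp_characteristic(d_open, config.flat_threshold))
    layers.append(mp_characteristic(d_close, config.flat_threshold))
    layers.append(mp_classification(d_open, d_close, config.flat_threshold))
    return np.stack(layers, axis=-1)
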