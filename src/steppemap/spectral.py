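"""Per-pixel spectral descriptors from RGB values (9 features per date).

The set combines the raw channels with visible-band indices used in
vegetation mapping: a soil coloration index (normalized R-G difference), the
analogous B-G coloration, green/red and blue/green band ratios, wideband
luminance, and the green leaf index.  Ratio denominators carry a small guard
``epsilon`` so every output is finite for all 8-bit inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SPECTRAL_FEATURE_NAMES = (
    "R",
    "G",
    "B",
    "colRG",
    "colBG",
    "GRratio",
    "BGratio",
    "pGluminance",
    "GreenLeaf",
)


@dataclass(frozen=True)
class SpectralConfig:
    feature_names: tuple[str, ...] = SPECTRAL_FEATURE_NAMES
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if tuple(self.feature_names) != SPECTRAL_FEATURE_NAMES:
            raise ValueError("spectral feature set is fixed (9 named features)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def compute_spectral(
    rgb_raster: np.ndarray, config: SpectralConfig | None = None
) -> np.ndarray:
    """Compute the 9 spectral feature layers for one RGB raster.

    Returns an H x W x 9 float array ordered as
    ``config.feature_names``.  Formulas::

        colRG       = (R - G) / (R + G + eps)
        colBG       = (B - G) / (B + G + eps)
        GRratio     = G / (R + eps)
        BGratio     = B / (G + eps)
        pGluminance = (R + G + B) / 3
        GreenLeaf   = (2G - R - B) / (2G + R + B + eps)
    """
    if config is None:
        config = SpectralConfig()
    rgb_raster = np.asarray(rgb_raster)
    if rgb_raster.ndim != 3 or rgb_raster.shape[2] != 3:
        raise ValueError("expected an H x W x 3 raster")
    rgb = rgb_raster.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    eps = config.epsilon
    out = np.empty(rgb.shape[:2] + (9,), dtype=np.float64)
    out[..., 0] = r
    out[..., 1] = g
    out[..., 2] = b
    out[..., 3] = (r - g) / (r + g + eps)
    out[..., 4] = (b - g) / (b + g + eps)
    out[..., 5] = g / (r + eps)
    out[..., 6] = b / (g + eps)
    out[..., 7] = (r + g + b) / 3.0
    out[..., 8] = (2.0 * g - r - b) / (2.0 * g + r + b + eps)
    return out
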