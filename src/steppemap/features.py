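"""Shared descriptor-extraction plumbing over an orthomosaic series.

Fused feature names follow ``<date>_<feature>`` with per-date feature names
coming from the three descriptor families (spectral, GLCM texture,
morphological profile).  Extraction is available at selected pixels (for
training/evaluation) and densely (for map inference); both paths share the
same code so values are identical.
"""

from __future__ import annotations

import numpy as np

from .imagery import OrthomosaicSeries, to_grayscale
from .model_eval import DescriptorStack, fuse_time_series
from .morphology import MORPH_FEATURE_NAMES, MorphologyConfig, compute_morphological_features
from .spectral import SPECTRAL_FEATURE_NAMES, SpectralConfig, compute_spectral
from .texture import TextureConfig, texture_features_at

ALL_FAMILIES = ("spectral", "texture", "morphology")


def family_feature_names(
    families=ALL_FAMILIES,
    texture_config: TextureConfig | None = None,
) -> list[str]:
    """Per-date feature names for the chosen descriptor families."""
    if texture_config is None:
        texture_config = TextureConfig()
    names: list[str] = []
    for fam in families:
        if fam == "spectral":
            names += list(SPECTRAL_FEATURE_NAMES)
        elif fam == "texture":
            names += texture_config.feature_names
        elif fam == "morphology":
            names += list(MORPH_FEATURE_NAMES)
        else:
            raise ValueError(f"unknown descriptor family: {fam}")
    return names


def _date_features_at(
    rgb: np.ndarray,
    pixels: np.ndarray,
    families,
    texture_config: TextureConfig,
    morph_config: MorphologyConfig,
    spectral_config: SpectralConfig,
    morph_cache: np.ndarray | None = None,
) -> np.ndarray:
    cols = []
    gray = None
    for fam in families:
        if fam == "spectral":
            vals = compute_spectral(rgb[pixels[:, 0], pixels[:, 1], :][:, None, :],
                                    spectral_config)[:, 0, :]
            cols.append(vals)
        elif fam == "texture":
            gray = to_grayscale(rgb) if gray is None else gray
            cols.append(texture_features_at(gray, pixels, texture_config))
        elif fam == "morphology":
            if morph_cache is None:
                gray = to_grayscale(rgb) if gray is None else gray
                morph_cache = compute_morphological_features(gray, morph_config)
            cols.append(morph_cache[pixels[:, 0], pixels[:, 1], :])
    return np.concatenate(cols, axis=1)


def compute_descriptors_at(
    series: OrthomosaicSeries,
    pixels: np.ndarray,
    families=ALL_FAMILIES,
    texture_config: TextureConfig | None = None,
    morph_config: MorphologyConfig | None = None,
    spectral_config: SpectralConfig | None = None,
) -> DescriptorStack:
    """Fused time-series descriptors at selected pixels: (N, T x d)."""
    texture_config = texture_config or TextureConfig()
    morph_config = morph_config or MorphologyConfig()
    spectral_config = spectral_config or SpectralConfig()
    pixels = np.asarray(pixels, dtype=np.intp)
    names = family_feature_names(families, texture_config)
    stacks = []
    for date, rgb in zip(series.dates, series.rasters):
        vals = _date_features_at(
            rgb, pixels, families, texture_config, morph_config, spectral_config
        )
        stacks.append(DescriptorStack(values=vals, names=names, date=date))
    return fuse_time_series(stacks)


def parse_feature_spec(
    feature_spec: list[str], dates: list[str]
) -> dict[str, dict[str, list[str]]]:
    """Split fused feature names into {date: {family: [per-date names]}}."""
    out: dict[str, dict[str, list[str]]] = {}
    for name in feature_spec:
        date = next((d for d in dates if name.startswith(d + "_")), None)
        if date is None:
            raise ValueError(f"feature {name} references an unavailable date")
        feat = name[len(date) + 1 :]
        if feat in SPECTRAL_FEATURE_NAMES:
            fam = "spectral"
        elif feat.startswith("GLCM_"):
            fam = "texture"
        elif feat.startswith("MP"):
            fam = "morphology"
        else:
            raise ValueError(f"feature {name} references an unknown family")
        out.setdefault(date, {}).setdefault(fam, []).append(feat)
    return out


def compute_spec_features_at(
    series: OrthomosaicSeries,
    pixels: np.ndarray,
    feature_spec: list[str],
    texture_config: TextureConfig | None = None,
    morph_config: MorphologyConfig | None = None,
    morph_caches: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Feature matrix for exactly the named fused features, in spec order.

    Only the descriptor families actually referenced are computed per date.
    ``morph_caches`` may hold precomputed full-raster morphology stacks keyed
    by date (morphological reconstruction is a whole-image operation).
    """
    texture_config = texture_config or TextureConfig()
    morph_config = morph_config or MorphologyConfig()
    pixels = np.asarray(pixels, dtype=np.intp)
    by_date = parse_feature_spec(feature_spec, series.dates)
    cols: dict[str, np.ndarray] = {}
    for date, rgb in zip(series.dates, series.rasters):
        if date not in by_date:
            continue
        fams = list(by_date[date])
        cache = (morph_caches or {}).get(date)
        vals = _date_features_at(
            rgb, pixels, fams, texture_config, morph_config, SpectralConfig(),
            morph_cache=cache,
        )
        names = [f"{date}_{n}" for n in family_feature_names(fams, texture_config)]
        for j, n in enumerate(names):
            cols[n] = vals[:, j]
    return np.column_stack([cols[n] for n in feature_spec])
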