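import numpy as np
import pytest

from steppemap.synthetic import SceneConfig, generate_scene_series


@pytest.fixture(scope="session")
def tiny_scene():
    """Small but complete scene: all four classes, plots, points, transect."""
    cfg = SceneConfig(
        height=192, width=192, n_plots=3, n_shrub_points=15, n_bare_points=8,
        transect_count=25, n_shrub_blobs=3, n_bare_patches=2,
        shrub_radius_px=(15, 25), bare_radius_px=(8, 14), min_spacing_m=2.0,
        seed=7,
    )
    series, geometry, labels = generate_scene_series(cfg)
    return cfg, series, geometry, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
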