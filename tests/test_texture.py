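import numpy as np
import pytest

from steppemap.texture import (
    GLCM_STATISTIC_NAMES,
    CooccurrenceMatrix,
    TextureConfig,
    compute_glcm,
    compute_texture_features,
    glcm_statistics,
    glcm_statistics_batch,
    texture_features_at,
)

from oracles import brute_force_glcm, literal_glcm_statistics


class TestComputeGLCM:
    def test_constant_window_single_diagonal_entry(self):
        m = compute_glcm(np.full((9, 9), 100.0), (-2, 2), 16)
        q = int(100 * 16 // 256)
        assert m.P[q, q] == pytest.approx(1.0)
        assert m.P.sum() == pytest.approx(1.0, abs=1e-9)

    def test_checkerboard_diagonal_offset_has_equal_parity_mass(self):
        board = np.indices((8, 8)).sum(axis=0) % 2 * 255.0
        m = compute_glcm(board, (1, 1), 2)
        # pairs along the diagonal connect equal-parity cells only
        assert m.P[0, 1] == 0.0 and m.P[1, 0] == 0.0
        assert m.P[0, 0] + m.P[1, 1] == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self, rng):
        win = rng.integers(0, 256, (8, 8)).astype(float)
        m = compute_glcm(win, (4, -4), 8)
        oracle = brute_force_glcm(win, (4, -4), 8)
        np.testing.assert_allclose(m.P, oracle, atol=1e-12)

    def test_symmetric_and_normalized(self, rng):
        win = rng.integers(0, 256, (17, 17)).astype(float)
        m = compute_glcm(win, (-4, 4), 16)
        np.testing.assert_allclose(m.P, m.P.T, atol=0)
        assert abs(m.P.sum() - 1.0) < 1e-9

    def test_offset_larger_than_window_is_an_error(self):
        with pytest.raises(ValueError, match="offset"):
            compute_glcm(np.zeros((5, 5)), (-6, 6), 8)


class TestGLCMStatistics:
    def test_degenerate_distribution(self):
        m = compute_glcm(np.full((9, 9), 40.0), (-2, 2), 16)
        s = glcm_statistics(m)
        assert s["energy"] == pytest.approx(1.0)
        assert s["entropy"] == pytest.approx(0.0, abs=1e-12)
        assert s["contrast"] == 0.0
        assert s["diss"] == 0.0
        assert s["homogeneity"] == pytest.approx(1.0)
        assert s["correlation"] == 0.0  # zero-variance convention

    def test_uniform_matrix_closed_form(self):
        k = 4
        s = glcm_statistics(CooccurrenceMatrix(np.full((k, k), 1 / k**2)))
        assert s["energy"] == pytest.approx(1 / k**2)
        assert s["entropy"] == pytest.approx(2 * np.log(k))

    def test_all_18_match_literal_formula_oracle(self, rng):
        for _ in range(20):
            raw = rng.random((4, 4))
            P = (raw + raw.T) / (raw + raw.T).sum()
            got = glcm_statistics(CooccurrenceMatrix(P))
            want = literal_glcm_statistics(P)
            for name in GLCM_STATISTIC_NAMES:
                assert got[name] == pytest.approx(want[name], abs=1e-10), name

    def test_unnormalized_matrix_is_an_error(self):
        with pytest.raises(ValueError, match="normalized"):
            CooccurrenceMatrix(np.ones((4, 4)))

    def test_value_range_invariants(self, rng):
        raw = rng.random((16, 16))
        P = (raw + raw.T) / (raw + raw.T).sum()
        s = glcm_statistics(CooccurrenceMatrix(P))
        assert 0 < s["energy"] <= 1
        assert s["entropy"] >= 0
        assert 0 < s["homogeneity"] <= 1
        assert min(s["variance"], s["contrast"], s["diss"]) >= 0
        assert 0 <= s["infMcorr2"] <= 1


class TestFeatureMaps:
    def test_exactly_54_layers_and_constant_raster(self):
        cfg = TextureConfig()
        out = compute_texture_features(np.full((64, 64), 77.0), cfg)
        assert out.shape == (64, 64, 54)
        names = cfg.feature_names
        assert len(names) == 54
        energy = out[..., names.index("GLCM_energy_17")]
        entropy = out[..., names.index("GLCM_entropy_17")]
        np.testing.assert_allclose(energy, 1.0)
        np.testing.assert_allclose(entropy, 0.0, atol=1e-12)

    def test_center_pixel_equals_manual_window_computation(self, rng):
        gray = rng.uniform(0, 255, (80, 80))
        cfg = TextureConfig()
        r, c = 40, 40
        feats = texture_features_at(gray, np.array([[r, c]]), cfg)[0]
        for s, (w, d) in enumerate(zip(cfg.window_sizes, cfg.offsets)):
            h = w // 2
            pad = max(cfg.window_sizes) // 2
            padded = np.pad(gray, pad, mode="reflect")
            win = padded[r + pad - h : r + pad + h + 1, c + pad - h : c + pad + h + 1]
            m = brute_force_glcm(win, (-d, d), cfg.levels)
            want = literal_glcm_statistics(m)
            got = dict(zip(GLCM_STATISTIC_NAMES, feats[s * 18 : (s + 1) * 18]))
            for name in GLCM_STATISTIC_NAMES:
                assert got[name] == pytest.approx(want[name], abs=1e-9), (name, w)

    def test_offset_sign_convention_is_immaterial(self, rng):
        win = rng.integers(0, 256, (17, 17)).astype(float)
        a = compute_glcm(win, (-4, 4), 16)
        b = compute_glcm(win, (4, -4), 16)
        np.testing.assert_allclose(a.P, b.P, atol=0)

    def test_translation_covariance_on_interior(self, rng):
        gray = rng.uniform(0, 255, (80, 80))
        cfg = TextureConfig(window_sizes=(17,), offsets=(4,))
        shift = 3
        a = texture_features_at(gray, np.array([[40, 40]]), cfg)
        b = texture_features_at(
            np.roll(gray, (-shift, -shift), axis=(0, 1)),
            np.array([[40 - shift, 40 - shift]]),
            cfg,
        )
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_small_raster_is_an_error(self):
        with pytest.raises(ValueError, match="smaller"):
            compute_texture_features(np.zeros((32, 32)))


def test_batch_statistics_match_single(rng):
    raw = rng.random((5, 8, 8))
    P = (raw + raw.transpose(0, 2, 1))
    P /= P.sum(axis=(1, 2), keepdims=True)
    batch = glcm_statistics_batch(P)
    for k in range(5):
        single = glcm_statistics(CooccurrenceMatrix(P[k]))
        np.testing.assert_allclose(batch[k], [single[n] for n in GLCM_STATISTIC_NAMES])
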