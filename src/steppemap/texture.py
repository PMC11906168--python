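"""Multiscale GLCM texture descriptors (18 statistics x 3 scales = 54 per date).

For every pixel, a gray-level co-occurrence matrix (GLCM) is accumulated over
the square analysis window centered on it, from pixel pairs at a fixed L-inf
distance positioned at 45 degrees, counted symmetrically.  Eighteen Haralick /
Conners statistics of that matrix form the texture descriptor; three window
sizes (17, 31, 61 px), each with its own pair distance (4, 8, 16 px), give the
multiscale set.

Gray levels are quantized into a fixed number of bins over the global [0, 255]
range (not per-window min-max), so values are comparable across windows.
Statistics use natural logarithms with the convention 0*log(0) = 0; on a
zero-variance window the correlation-type statistics are defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GLCM_STATISTIC_NAMES = (
    "energy",
    "entropy",
    "correlation",
    "homogeneity",
    "contrast",
    "clShade",
    "clProminence",
    "Hcorrelation",
    "mean",
    "variance",
    "diss",
    "sumAvg",
    "sumVar",
    "sumEnt",
    "diffOfEntropies",
    "diffOfVar",
    "infMcorr1",
    "infMcorr2",
)


@dataclass(frozen=True)
class TextureConfig:
    """Multiscale GLCM configuration.

    One pair offset per window size; the 45-degree direction means the pair
    offset is ``(-d, +d)`` in (row, col).  Symmetric accumulation makes the
    sign convention immaterial.
    """

    window_sizes: tuple[int, ...] = (17, 31, 61)
    offsets: tuple[int, ...] = (4, 8, 16)
    direction_deg: float = 45.0
    levels: int = 16

    def __post_init__(self) -> None:
        if len(self.window_sizes) != len(self.offsets):
            raise ValueError("one offset per window size")
        if any(w % 2 == 0 for w in self.window_sizes):
            raise ValueError("window sizes must be odd")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if any(d >= w for w, d in zip(self.window_sizes, self.offsets)):
            raise ValueError("offset larger than window")

    @property
    def feature_names(self) -> list[str]:
        return [
            f"GLCM_{stat}_{w}"
            for w in self.window_sizes
            for stat in GLCM_STATISTIC_NAMES
        ]


@dataclass
class CooccurrenceMatrix:
    """Normalized symmetric co-occurrence matrix over quantized gray levels."""

    P: np.ndarray  # levels x levels, sums to 1

    def __post_init__(self) -> None:
        total = float(self.P.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("co-occurrence matrix must be normalized")

    @property
    def levels(self) -> int:
        return self.P.shape[0]

    @property
    def p_x(self) -> np.ndarray:
        return self.P.sum(axis=1)

    @property
    def p_y(self) -> np.ndarray:
        return self.P.sum(axis=0)


def quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Quantize gray values from the fixed global [0, 255] range into bins."""
    q = np.floor(np.asarray(gray, dtype=np.float64) * levels / 256.0)
    return np.clip(q, 0, levels - 1).astype(np.intp)


def compute_glcm(
    window: np.ndarray, offset: tuple[int, int], levels: int
) -> CooccurrenceMatrix:
    """Symmetric normalized GLCM of one fully-populated gray window.

    Every valid pixel pair ``(p, p + offset)`` is counted once in each
    direction.  Gray values are quantized over the global [0, 255] range.
    """
    window = np.asarray(window, dtype=np.float64)
    n_r, n_c = window.shape
    dr, dc = offset
    if abs(dr) >= n_r or abs(dc) >= n_c:
        raise ValueError("offset larger than window")
    q = quantize(window, levels)
    r0, r1 = max(0, -dr), n_r - max(0, dr)
    c0, c1 = max(0, -dc), n_c - max(0, dc)
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    counts = np.bincount((a * levels + b).ravel(), minlength=levels * levels)
    counts = counts.reshape(levels, levels).astype(np.float64)
    counts = counts + counts.T  # symmetric accumulation
    return CooccurrenceMatrix(counts / counts.sum())


class _StatTables:
    """Cached index tables for batched statistic evaluation at one level count."""

    _cache: dict[int, "_StatTables"] = {}

    def __init__(self, levels: int) -> None:
        i = np.arange(levels, dtype=np.float64)
        self.i = i
        self.ii, self.jj = np.meshgrid(i, i, indexing="ij")
        self.iso_sum = (self.ii + self.jj).astype(np.intp)  # i+j in 0..2L-2
        self.abs_diff = np.abs(self.ii - self.jj).astype(np.intp)  # |i-j|
        self.homog_w = 1.0 / (1.0 + (self.ii - self.jj) ** 2)
        self.contrast_w = (self.ii - self.jj) ** 2
        self.diss_w = np.abs(self.ii - self.jj)
        self.prod_w = self.ii * self.jj
        self.k_sum = np.arange(2 * levels - 1, dtype=np.float64)
        self.k_diff = np.arange(levels, dtype=np.float64)
        # one-hot selectors for the diagonal distributions
        self.sel_sum = (
            self.iso_sum[None, :, :] == np.arange(2 * levels - 1)[:, None, None]
        ).astype(np.float64)
        self.sel_diff = (
            self.abs_diff[None, :, :] == np.arange(levels)[:, None, None]
        ).astype(np.float64)

    @classmethod
    def get(cls, levels: int) -> "_StatTables":
        if levels not in cls._cache:
            cls._cache[levels] = cls(levels)
        return cls._cache[levels]


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * ln(p) with the 0*log(0) = 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def glcm_statistics_batch(P: np.ndarray) -> np.ndarray:
    """The 18 GLCM statistics for a batch of matrices (N, L, L) -> (N, 18)."""
    P = np.asarray(P, dtype=np.float64)
    if P.ndim == 2:
        P = P[None]
    n, levels, _ = P.shape
    t = _StatTables.get(levels)
    out = np.empty((n, 18), dtype=np.float64)

    px = P.sum(axis=2)  # (n, L)
    py = P.sum(axis=1)
    mu_x = px @ t.i
    mu_y = py @ t.i
    var_x = ((t.i[None, :] - mu_x[:, None]) ** 2 * px).sum(axis=1)
    var_y = ((t.i[None, :] - mu_y[:, None]) ** 2 * py).sum(axis=1)
    sig = np.sqrt(var_x * var_y)

    out[:, 0] = (P**2).sum(axis=(1, 2))  # energy
    hxy = -_xlogx(P).sum(axis=(1, 2))
    out[:, 1] = hxy  # entropy
    cov = (P * t.prod_w).sum(axis=(1, 2)) - mu_x * mu_y
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(sig > 1e-12, cov / np.where(sig > 0, sig, 1.0), 0.0)
    out[:, 2] = corr  # correlation
    out[:, 3] = (P * t.homog_w).sum(axis=(1, 2))  # homogeneity
    out[:, 4] = (P * t.contrast_w).sum(axis=(1, 2))  # contrast
    dev = t.ii[None] + t.jj[None] - (mu_x + mu_y)[:, None, None]
    out[:, 5] = (dev**3 * P).sum(axis=(1, 2))  # cluster shade
    out[:, 6] = (dev**4 * P).sum(axis=(1, 2))  # cluster prominence
    out[:, 7] = corr  # Haralick correlation: same closed form, kept by name
    out[:, 8] = mu_x  # mean
    out[:, 9] = var_x  # variance
    out[:, 10] = (P * t.diss_w).sum(axis=(1, 2))  # dissimilarity

    p_sum = np.einsum("kij,nij->nk", t.sel_sum, P)
    p_diff = np.einsum("kij,nij->nk", t.sel_diff, P)
    sum_avg = p_sum @ t.k_sum
    out[:, 11] = sum_avg
    out[:, 12] = ((t.k_sum[None, :] - sum_avg[:, None]) ** 2 * p_sum).sum(axis=1)
    out[:, 13] = -_xlogx(p_sum).sum(axis=1)  # sum entropy
    out[:, 14] = -_xlogx(p_diff).sum(axis=1)  # difference entropy
    mu_d = p_diff @ t.k_diff
    out[:, 15] = ((t.k_diff[None, :] - mu_d[:, None]) ** 2 * p_diff).sum(axis=1)

    hx = -_xlogx(px).sum(axis=1)
    hy = -_xlogx(py).sum(axis=1)
    pxpy = px[:, :, None] * py[:, None, :]
    log_pxpy = np.zeros_like(pxpy)
    nz = pxpy > 0
    log_pxpy[nz] = np.log(pxpy[nz])
    hxy1 = -(P * log_pxpy).sum(axis=(1, 2))
    hxy2 = -_xlogx(pxpy).sum(axis=(1, 2))
    hmax = np.maximum(hx, hy)
    with np.errstate(invalid="ignore", divide="ignore"):
        imc1 = np.where(hmax > 1e-12, (hxy - hxy1) / np.where(hmax > 0, hmax, 1.0), 0.0)
    out[:, 16] = imc1
    out[:, 17] = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, None))
    return out


def glcm_statistics(m: CooccurrenceMatrix) -> dict[str, float]:
    """The 18 statistics of one normalized co-occurrence matrix, by name."""
    vals = glcm_statistics_batch(m.P)[0]
    return dict(zip(GLCM_STATISTIC_NAMES, vals))


# ---------------------------------------------------------------------------
# raster-level extraction


def _pair_code_image(q: np.ndarray, d: int, levels: int) -> np.ndarray:
    """Code image c[p] = q[p] * L + q[p + (-d, +d)] on valid positions.

    Row r of the returned array corresponds to row ``r + d`` of ``q``;
    column c corresponds to column ``c`` of ``q``.
    """
    a = q[d:, : q.shape[1] - d]
    b = q[: q.shape[0] - d, d:]
    return a * levels + b


def texture_features_at(
    gray: np.ndarray,
    pixels: np.ndarray,
    config: TextureConfig | None = None,
    batch: int = 4096,
) -> np.ndarray:
    """Texture descriptors at selected pixels.

    ``pixels`` is an (N, 2) integer array of (row, col) indices into ``gray``.
    The raster is reflect-padded by half the largest window so every pixel has
    a fully populated analysis window.  Returns (N, 54).
    """
    if config is None:
        config = TextureConfig()
    gray = np.asarray(gray, dtype=np.float64)
    pixels = np.asarray(pixels, dtype=np.intp)
    w_max = max(config.window_sizes)
    if min(gray.shape) < 1:
        raise ValueError("empty raster")
    pad = w_max // 2
    padded = np.pad(gray, pad, mode="reflect")
    q = quantize(padded, config.levels)
    n_stats = len(GLCM_STATISTIC_NAMES)
    out = np.empty((len(pixels), n_stats * len(config.window_sizes)))
    lv = config.levels
    for s, (w, d) in enumerate(zip(config.window_sizes, config.offsets)):
        code = _pair_code_image(q, d, lv)
        h = w // 2
        # window centered at padded pixel (r+pad, c+pad); valid first-pixel
        # positions of a pair span a (w-d) x (w-d) block of the code image.
        n_pairs = (w - d) * (w - d)
        for start in range(0, len(pixels), batch):
            chunk = pixels[start : start + batch]
            mats = np.empty((len(chunk), lv, lv))
            for k, (r, c) in enumerate(chunk):
                rp, cp = r + pad, c + pad
                sub = code[rp - h : rp + h + 1 - d, cp - h : cp + h + 1 - d]
                counts = np.bincount(sub.ravel(), minlength=lv * lv).reshape(lv, lv)
                counts = counts + counts.T
                mats[k] = counts / (2.0 * n_pairs)
            out[start : start + len(chunk), s * n_stats : (s + 1) * n_stats] = (
                glcm_statistics_batch(mats)
            )
    return out


def compute_texture_features(
    gray_raster: np.ndarray, config: TextureConfig | None = None
) -> np.ndarray:
    """Dense 54-layer texture feature stack (H, W, 54) for one raster.

    Reflect padding keeps the output full-size; use :func:`validity_mask` to
    flag pixels whose analysis window reached into the padded margin.
    """
    if config is None:
        config = TextureConfig()
    gray_raster = np.asarray(gray_raster, dtype=np.float64)
    h, w = gray_raster.shape
    if min(h, w) < max(config.window_sizes):
        raise ValueError("raster smaller than largest analysis window")
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pixels = np.column_stack([rows.ravel(), cols.ravel()])
    feats = texture_features_at(gray_raster, pixels, config)
    return feats.reshape(h, w, -1)


def validity_mask(
    shape: tuple[int, int], config: TextureConfig | None = None
) -> np.ndarray:
    """True where the largest analysis window lies fully inside the raster."""
    if config is None:
        config = TextureConfig()
    h, w = shape
    m = np.zeros((h, w), dtype=bool)
    half = max(config.window_sizes) // 2
    m[half : h - half, half : w - half] = True
    return m
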