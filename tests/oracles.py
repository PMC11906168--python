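"""Independent brute-force oracles used by the tests.

Everything here is written as literal definitions (explicit loops, no shared
code with the package) so it can serve as an independent reference for the
vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_glcm(window, offset, levels):
    """Exhaustive pair enumeration: symmetric, normalized co-occurrence."""
    window = np.asarray(window, dtype=float)
    n_r, n_c = window.shape
    q = np.clip(np.floor(window * levels / 256.0), 0, levels - 1).astype(int)
    dr, dc = offset
    counts = np.zeros((levels, levels))
    for r in range(n_r):
        for c in range(n_c):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < n_r and 0 <= c2 < n_c:
                counts[q[r, c], q[r2, c2]] += 1
                counts[q[r2, c2], q[r, c]] += 1
    return counts / counts.sum()


def _log(x):
    return math.log(x) if x > 0 else 0.0


def literal_glcm_statistics(P):
    """The 18 texture statistics as literal sums over the matrix."""
    P = np.asarray(P, dtype=float)
    L = P.shape[0]
    px = [sum(P[i, j] for j in range(L)) for i in range(L)]
    py = [sum(P[i, j] for i in range(L)) for j in range(L)]
    mu_x = sum(i * px[i] for i in range(L))
    mu_y = sum(j * py[j] for j in range(L))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(L))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(L))
    sig = math.sqrt(var_x * var_y)

    energy = sum(P[i, j] ** 2 for i in range(L) for j in range(L))
    entropy = -sum(P[i, j] * _log(P[i, j]) for i in range(L) for j in range(L))
    if sig > 1e-12:
        correlation = sum(
            (i - mu_x) * (j - mu_y) * P[i, j] for i in range(L) for j in range(L)
        ) / sig
        hcorr = (
            sum(i * j * P[i, j] for i in range(L) for j in range(L)) - mu_x * mu_y
        ) / sig
    else:
        correlation = hcorr = 0.0
    homogeneity = sum(
        P[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L)
    )
    contrast = sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L))
    cl_shade = sum(
        (i + j - mu_x - mu_y) ** 3 * P[i, j] for i in range(L) for j in range(L)
    )
    cl_prom = sum(
        (i + j - mu_x - mu_y) ** 4 * P[i, j] for i in range(L) for j in range(L)
    )
    diss = sum(abs(i - j) * P[i, j] for i in range(L) for j in range(L))

    p_sum = [0.0] * (2 * L - 1)
    p_diff = [0.0] * L
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]
    sum_avg = sum(k * p_sum[k] for k in range(2 * L - 1))
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2 * L - 1))
    sum_ent = -sum(p_sum[k] * _log(p_sum[k]) for k in range(2 * L - 1))
    diff_ent = -sum(p_diff[k] * _log(p_diff[k]) for k in range(L))
    mu_d = sum(k * p_diff[k] for k in range(L))
    diff_var = sum((k - mu_d) ** 2 * p_diff[k] for k in range(L))

    hx = -sum(px[i] * _log(px[i]) for i in range(L))
    hy = -sum(py[j] * _log(py[j]) for j in range(L))
    hxy1 = -sum(
        P[i, j] * _log(px[i] * py[j]) for i in range(L) for j in range(L)
    )
    hxy2 = -sum(
        px[i] * py[j] * _log(px[i] * py[j]) for i in range(L) for j in range(L)
    )
    hmax = max(hx, hy)
    imc1 = (entropy - hxy1) / hmax if hmax > 1e-12 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))

    return {
        "energy": energy, "entropy": entropy, "correlation": correlation,
        "homogeneity": homogeneity, "contrast": contrast, "clShade": cl_shade,
        "clProminence": cl_prom, "Hcorrelation": hcorr, "mean": mu_x,
        "variance": var_x, "diss": diss, "sumAvg": sum_avg, "sumVar": sum_var,
        "sumEnt": sum_ent, "diffOfEntropies": diff_ent, "diffOfVar": diff_var,
        "infMcorr1": imc1, "infMcorr2": imc2,
    }


def brute_force_circle_pixels(center, radius, origin_x, origin_y, pixel_size, shape):
    """Enumerate every pixel whose center is within the circle."""
    out = []
    for r in range(shape[0]):
        for c in range(shape[1]):
            x = origin_x + (c + 0.5) * pixel_size
            y = origin_y - (r + 0.5) * pixel_size
            if (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius**2:
                out.append((r, c))
    return set(out)


def point_in_polygon(x, y, vertices):
    """Ray-casting point-in-polygon (boundary treated as inside via eps check)."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # on-segment check
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 \
                and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
            return True
        if (y1 > y) != (y2 > y):
            xin = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xin:
                inside = not inside
    return inside
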