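"""Independent brute-force oracles used to validate the texture code.

Everything here is deliberately written as plain loops over pixels/cells,
sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_bruteforce(levels_img: np.ndarray, levels: int, distance: int, orientation: int) -> np.ndarray:
    """Normalized GLCM by exhaustive enumeration of ordered pixel pairs."""
    dr, dc = OFFSETS[orientation]
    dr, dc = dr * distance, dc * distance
    h, w = levels_img.shape
    counts = np.zeros((levels, levels))
    n = 0
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[levels_img[r, c], levels_img[r2, c2]] += 1
                n += 1
    if n == 0:
        raise ValueError("no pairs")
    return counts / n


def glcm_props_bruteforce(p: np.ndarray) -> tuple[float, float | None, float, float]:
    """(contrast, correlation, energy, homogeneity) by explicit cell loops.

    correlation is None when either marginal is degenerate.
    """
    levels = p.shape[0]
    contrast = energy = homogeneity = 0.0
    mu_i = mu_j = 0.0
    for i in range(levels):
        for j in range(levels):
            contrast += p[i, j] * (i - j) ** 2
            energy += p[i, j] ** 2
            homogeneity += p[i, j] / (1 + abs(i - j))
            mu_i += i * p[i, j]
            mu_j += j * p[i, j]
    var_i = var_j = cov = 0.0
    for i in range(levels):
        for j in range(levels):
            var_i += p[i, j] * (i - mu_i) ** 2
            var_j += p[i, j] * (j - mu_j) ** 2
            cov += p[i, j] * (i - mu_i) * (j - mu_j)
    if var_i <= 0 or var_j <= 0:
        return contrast, None, energy, homogeneity
    return contrast, cov / math.sqrt(var_i * var_j), energy, homogeneity


def moments_bruteforce(values: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, sd_{n-1}, kurtosis m4/m2^2, skewness m3/m2^1.5) via direct sums."""
    values = [float(v) for v in np.ravel(values)]
    n = len(values)
    mean = sum(values) / n
    m2 = sum((v - mean) ** 2 for v in values) / n
    m3 = sum((v - mean) ** 3 for v in values) / n
    m4 = sum((v - mean) ** 4 for v in values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1)) if n > 1 else 0.0
    if m2 == 0:
        return mean, sd, float("nan"), float("nan")
    return mean, sd, m4 / m2**2, m3 / m2**1.5


def entropy_bruteforce(values01: np.ndarray) -> float:
    """Base-2 Shannon entropy of the 256-bin histogram of an 8-bit requantized image."""
    q = [int(round(float(v) * 255)) for v in np.ravel(values01)]
    n = len(q)
    h = 0.0
    for level in set(q):
        p = q.count(level) / n
        h -= p * math.log2(p)
    return h


def auc_mannwhitney(scores: np.ndarray, truths01: np.ndarray) -> float:
    """AUC through the Mann–Whitney U statistic (rank-based, tie-aware)."""
    from scipy.stats import mannwhitneyu

    scores = np.asarray(scores, dtype=float)
    truths01 = np.asarray(truths01)
    pos = scores[truths01 == 1]
    neg = scores[truths01 == 0]
    u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))
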