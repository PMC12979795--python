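"""Per-channel texture parameters: first-order statistics and GLCM properties.

Each QC-accepted, min–max-normalized single-channel image is summarized by 17
numbers: five first-order statistics (mean, standard deviation, kurtosis,
skewness, Shannon entropy of the 8-bit histogram) and, for each pixel
distance d in {1, 12, 30}, four gray-level co-occurrence properties
(contrast, correlation, energy, homogeneity) averaged over the four
orientations 0°, 45°, 90°, 135°.

Offset conventions follow the classic co-occurrence definition with Chebyshev
distance d on the diagonals: 0° → (0, +d), 45° → (−d, +d), 90° → (−d, 0),
135° → (−d, −d); pairs are ordered (non-symmetric matrix) by default, with a
symmetric mode available. Gray levels are obtained by uniform binning of
[0, 1] into L levels (default L = 8); the choice of L and symmetry is carried
in the extraction config so it is recorded with every feature table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .fov_io import CHANNEL_ORDER, ChannelImage, FovImage, minmax_normalize

DEFAULT_DISTANCES: tuple[int, ...] = (1, 12, 30)
DEFAULT_LEVELS: int = 8
ORIENTATIONS_DEG: tuple[int, ...] = (0, 45, 90, 135)

#: Unit offsets (row, col) per orientation; multiply by the distance.
OFFSETS: dict[int, tuple[int, int]] = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

FIRST_ORDER_NAMES: tuple[str, ...] = ("mean", "sd", "kurtosis", "skewness", "entropy")
GLCM_PROP_NAMES: tuple[str, ...] = ("contrast", "correlation", "energy", "homogeneity")


class FeatureError(ValueError):
    """Raised when features cannot be computed (degenerate or invalid input)."""


class GlcmError(ValueError):
    """Raised when a co-occurrence matrix has no contributing pixel pairs."""


@dataclass(frozen=True)
class Glcm:
    """Normalized co-occurrence matrix for one (distance, orientation) pair."""

    matrix: np.ndarray  # (L, L), entries >= 0, sums to 1
    levels: int
    distance_px: int
    orientation_deg: int
    pair_count: int


class FirstOrderStats(NamedTuple):
    mean: float
    sd: float
    kurtosis: float
    skewness: float
    entropy: float
    degenerate: bool = False


class GlcmProps(NamedTuple):
    contrast: float
    correlation: float
    energy: float
    homogeneity: float
    degenerate_correlation: bool = False


def feature_names(
    channel: str | None = None, distances: Sequence[int] = DEFAULT_DISTANCES
) -> list[str]:
    """The published 17-name contract, optionally prefixed with a channel."""
    names = list(FIRST_ORDER_NAMES)
    for d in distances:
        names.extend(f"{prop}_d{d}" for prop in GLCM_PROP_NAMES)
    if channel is not None:
        names = [f"{channel.lower()}_{n}" for n in names]
    return names


def first_order_stats(img: ChannelImage) -> FirstOrderStats:
    """First-order statistics of a normalized channel.

    sd uses the n−1 denominator; skewness m3/m2^1.5 and non-excess kurtosis
    m4/m2^2 use biased population moments (a Gaussian has kurtosis 3);
    entropy is the base-2 Shannon entropy of the 256-bin histogram of the
    image re-quantized to 8 bit. A zero-variance image yields sentinel 0 for
    skewness/kurtosis and ``degenerate=True``.
    """
    pixels = np.asarray(img.pixels, dtype=np.float64).ravel()
    if pixels.size == 0:
        raise FeatureError("empty image")
    mean = float(pixels.mean())
    sd = float(pixels.std(ddof=1)) if pixels.size > 1 else 0.0
    quantized = np.clip(np.round(pixels * 255.0), 0, 255).astype(np.int64)
    hist = np.bincount(quantized, minlength=256)
    entropy = float(sps.entropy(hist / hist.sum(), base=2))
    if np.all(pixels == pixels[0]):
        return FirstOrderStats(mean, 0.0, 0.0, 0.0, entropy, degenerate=True)
    skewness = float(sps.skew(pixels, bias=True))
    kurtosis = float(sps.kurtosis(pixels, fisher=False, bias=True))
    return FirstOrderStats(mean, sd, kurtosis, skewness, entropy)


def quantize_channel(img: ChannelImage, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Uniformly bin a normalized [0, 1] channel into integer gray levels."""
    if not img.normalized:
        raise FeatureError("channel must be min–max normalized before quantization")
    pixels = np.asarray(img.pixels, dtype=np.float64)
    return np.minimum((pixels * levels).astype(np.int64), levels - 1)


def _glcm_from_levels(
    q: np.ndarray, levels: int, distance_px: int, orientation_deg: int, symmetric: bool
) -> Glcm:
    dr, dc = OFFSETS[orientation_deg]
    dr *= distance_px
    dc *= distance_px
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise GlcmError(
            f"no pixel pairs for distance {distance_px} at {orientation_deg}° on image of shape {(h, w)}"
        )
    src = q[r0:r1, c0:c1]
    dst = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    codes = src.ravel() * levels + dst.ravel()
    counts = np.bincount(codes, minlength=levels * levels).reshape(levels, levels).astype(np.float64)
    pair_count = src.size
    if symmetric:
        counts = counts + counts.T
        pair_count *= 2
    return Glcm(
        matrix=counts / counts.sum(),
        levels=levels,
        distance_px=distance_px,
        orientation_deg=orientation_deg,
        pair_count=pair_count,
    )


def compute_glcm(
    img: ChannelImage,
    distance_px: int,
    orientation_deg: int,
    levels: int = DEFAULT_LEVELS,
    symmetric: bool = False,
) -> Glcm:
    """Gray-level co-occurrence matrix for one (distance, orientation)."""
    if distance_px < 1:
        raise GlcmError("distance_px must be >= 1")
    if orientation_deg not in OFFSETS:
        raise GlcmError(f"orientation must be one of {sorted(OFFSETS)}")
    return _glcm_from_levels(quantize_channel(img, levels), levels, distance_px, orientation_deg, symmetric)


def glcm_props(g: Glcm) -> GlcmProps:
    """Contrast, correlation, energy and homogeneity of a normalized GLCM.

    correlation = Σ P(i,j)(i−µ_i)(j−µ_j)/(σ_i σ_j); if either marginal has
    zero variance the correlation is undefined and the sentinel 0 is returned
    with ``degenerate_correlation=True``.
    """
    p = np.asarray(g.matrix, dtype=np.float64)
    levels = p.shape[0]
    i = np.arange(levels, dtype=np.float64)[:, None]
    j = np.arange(levels, dtype=np.float64)[None, :]
    contrast = float(np.sum(p * (i - j) ** 2))
    energy = float(np.sum(p * p))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    idx = np.arange(levels, dtype=np.float64)
    mu_i = float(pi @ idx)
    mu_j = float(pj @ idx)
    var_i = float(pi @ (idx - mu_i) ** 2)
    var_j = float(pj @ (idx - mu_j) ** 2)
    if var_i <= 0 or var_j <= 0:
        return GlcmProps(contrast, 0.0, energy, homogeneity, degenerate_correlation=True)
    correlation = float(np.sum(p * (i - mu_i) * (j - mu_j)) / np.sqrt(var_i * var_j))
    return GlcmProps(contrast, correlation, energy, homogeneity)


def extract_features(
    img: ChannelImage,
    distances_px: Sequence[int] = DEFAULT_DISTANCES,
    levels: int = DEFAULT_LEVELS,
    symmetric: bool = False,
) -> np.ndarray:
    """The 17-value texture vector of one normalized channel, in contract
    order: mean, sd, kurtosis, skewness, entropy, then per distance the plain
    mean over the four orientations of contrast, correlation, energy and
    homogeneity."""
    if img.degenerate:
        raise FeatureError(f"channel {img.channel_name} is degenerate (constant image)")
    if not img.normalized:
        raise FeatureError("channel must be min–max normalized")
    fos = first_order_stats(img)
    if fos.degenerate:
        raise FeatureError(f"channel {img.channel_name} has zero variance")
    values = [fos.mean, fos.sd, fos.kurtosis, fos.skewness, fos.entropy]
    q = quantize_channel(img, levels)
    for d in distances_px:
        props = np.zeros((len(ORIENTATIONS_DEG), 4), dtype=np.float64)
        for k, orient in enumerate(ORIENTATIONS_DEG):
            g = _glcm_from_levels(q, levels, d, orient, symmetric)
            props[k] = glcm_props(g)[:4]
        values.extend(props.mean(axis=0))
    return np.asarray(values, dtype=np.float64)


def featurize_fov(
    fov: FovImage,
    channel_set: Sequence[str] = CHANNEL_ORDER,
    distances_px: Sequence[int] = DEFAULT_DISTANCES,
    levels: int = DEFAULT_LEVELS,
    symmetric: bool = False,
) -> np.ndarray:
    """Concatenated texture vector of a QC-accepted FoV.

    Channels are always concatenated in the fixed order CARS, TPEF, SHG
    restricted to ``channel_set``; the result has length 17 × |channel_set|.
    """
    requested = set(channel_set)
    if not requested:
        raise FeatureError("channel_set must not be empty")
    unknown = requested - set(CHANNEL_ORDER)
    if unknown:
        raise FeatureError(f"unknown channels {sorted(unknown)}")
    parts = []
    for name in CHANNEL_ORDER:
        if name not in requested:
            continue
        channel = minmax_normalize(
            ChannelImage(pixels=fov.channels[name], channel_name=name)
        )
        parts.append(extract_features(channel, distances_px, levels, symmetric))
    return np.concatenate(parts)


def fov_feature_names(
    channel_set: Sequence[str] = CHANNEL_ORDER, distances: Sequence[int] = DEFAULT_DISTANCES
) -> list[str]:
    """Column names matching :func:`featurize_fov` output order."""
    names: list[str] = []
    for name in CHANNEL_ORDER:
        if name in set(channel_set):
            names.extend(feature_names(name, distances))
    return names
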