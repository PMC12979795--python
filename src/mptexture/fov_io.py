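"""Field-of-view image containers, RGB TIFF round trips, normalization and QC.

A field of view (FoV) is one acquired image tile carrying three aligned 8-bit
channels: CARS (lipid-rich structures, encoded red), TPEF (cellular
autofluorescence, green) and SHG (fibrillar collagen, blue). This module owns
the on-disk RGB TIFF representation, channel splitting, min–max intensity
normalization, and the quality-control rule that rejects tiles dominated by
background (tissue borders, holes) or detector saturation before any texture
statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

#: Fixed channel ordering used everywhere downstream (feature concatenation,
#: model naming, CSV column order).
CHANNEL_ORDER: tuple[str, str, str] = ("CARS", "TPEF", "SHG")

# RGB plane -> channel: red=CARS, green=TPEF, blue=SHG.
_RGB_PLANES = {"CARS": 0, "TPEF": 1, "SHG": 2}


class FormatError(ValueError):
    """Raised when a file is not a readable three-plane RGB TIFF."""


class DegenerateImageError(ValueError):
    """Raised when an operation requires a non-constant image."""


@dataclass
class FovImage:
    """One three-channel field of view plus acquisition metadata.

    ``channels`` maps each name in :data:`CHANNEL_ORDER` to a 2-D ``uint8``
    array; all three share one shape. ``tile`` is the (row, col) position on
    the sample's tiling grid for mapped (border) samples, ``None`` otherwise.
    """

    channels: dict[str, np.ndarray]
    patient_id: str | None = None
    sample_kind: str | None = None  # liver | tumor | border
    tile: tuple[int, int] | None = None
    true_label: str | None = None  # liver | tumor
    pixel_size: float = 1.0  # µm per pixel

    def __post_init__(self) -> None:
        if set(self.channels) != set(CHANNEL_ORDER):
            raise ValueError(f"channels must be exactly {CHANNEL_ORDER}, got {sorted(self.channels)}")
        shapes = {self.channels[c].shape for c in CHANNEL_ORDER}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name in CHANNEL_ORDER:
            arr = np.asarray(self.channels[name])
            if arr.ndim != 2:
                raise ValueError(f"channel {name} is not 2-D")
            if arr.dtype != np.uint8:
                if arr.min() < 0 or arr.max() > 255:
                    raise ValueError(f"channel {name} outside [0, 255]")
                arr = arr.astype(np.uint8)
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels["CARS"].shape

    def to_rgb(self) -> np.ndarray:
        """Stack the channels into an (H, W, 3) RGB array."""
        return np.stack([self.channels[c] for c in CHANNEL_ORDER], axis=-1)


@dataclass
class ChannelImage:
    """A single channel, before (uint8 in [0,255]) or after (float in [0,1])
    min–max normalization. ``degenerate`` flags a constant source image whose
    normalization is undefined; such images must be QC-rejected upstream."""

    pixels: np.ndarray
    channel_name: str
    normalized: bool = False
    degenerate: bool = False


@dataclass(frozen=True)
class QcReport:
    """Outcome of the tile-level quality control rule."""

    accepted: bool
    background_fraction: float
    saturated_fraction: float
    reason: str  # ok | border_or_hole | saturation | constant

    def __post_init__(self) -> None:
        if self.accepted != (self.reason == "ok"):
            raise ValueError("accepted flag inconsistent with reason")


def read_fov(
    path: str | Path,
    patient_id: str | None = None,
    sample_kind: str | None = None,
    tile: tuple[int, int] | None = None,
    true_label: str | None = None,
    pixel_size: float = 1.0,
) -> FovImage:
    """Read an RGB TIFF into a :class:`FovImage` (red→CARS, green→TPEF, blue→SHG)."""
    try:
        arr = tifffile.imread(str(path))
    except (OSError, ValueError) as exc:  # unreadable / not a TIFF
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise FormatError(f"{path}: expected an RGB image (H, W, 3), got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit data, got {arr.dtype}")
    channels = {name: np.ascontiguousarray(arr[..., plane]) for name, plane in _RGB_PLANES.items()}
    return FovImage(
        channels=channels,
        patient_id=patient_id,
        sample_kind=sample_kind,
        tile=tile,
        true_label=true_label,
        pixel_size=pixel_size,
    )


def write_fov(fov: FovImage, path: str | Path) -> None:
    """Write a :class:`FovImage` as an 8-bit RGB TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), fov.to_rgb(), photometric="rgb")


def split_channels(fov: FovImage) -> tuple[ChannelImage, ChannelImage, ChannelImage]:
    """Split a FoV into its three single-channel images, in fixed order
    (CARS, TPEF, SHG) regardless of call site."""
    return tuple(  # type: ignore[return-value]
        ChannelImage(pixels=fov.channels[name].copy(), channel_name=name)
        for name in CHANNEL_ORDER
    )


def recombine_channels(channels: tuple[ChannelImage, ...], **metadata) -> FovImage:
    """Inverse of :func:`split_channels`; channels may arrive in any order."""
    by_name = {c.channel_name: c.pixels for c in channels}
    return FovImage(channels={name: by_name[name] for name in CHANNEL_ORDER}, **metadata)


def minmax_normalize(img: ChannelImage) -> ChannelImage:
    """Min–max normalize a single channel to [0, 1].

    A constant input has no defined normalization; it is returned as an
    all-zero image with ``degenerate=True`` so the caller can QC-reject it
    rather than silently propagating zeros. Idempotent on normalized images.
    """
    pixels = np.asarray(img.pixels, dtype=np.float64)
    lo = pixels.min()
    hi = pixels.max()
    if hi == lo:
        return ChannelImage(
            pixels=np.zeros_like(pixels),
            channel_name=img.channel_name,
            normalized=True,
            degenerate=True,
        )
    return ChannelImage(
        pixels=(pixels - lo) / (hi - lo),
        channel_name=img.channel_name,
        normalized=True,
        degenerate=False,
    )


def qc_filter(
    fov: FovImage,
    tau_bg: float = 0.25,
    tau_sat: float = 0.05,
    background_level: int = 2,
) -> QcReport:
    """Tile-level quality control.

    Rejects a FoV when (in order of precedence) any channel is constant, the
    TPEF background fraction (pixels below ``background_level``) exceeds
    ``tau_bg`` — the signature of tissue borders and holes — or the fraction
    of pixels saturated (value 255 in any channel) exceeds ``tau_sat``.
    """
    tpef = fov.channels["TPEF"]
    background_fraction = float(np.mean(tpef < background_level))
    saturated = np.zeros(fov.shape, dtype=bool)
    for name in CHANNEL_ORDER:
        saturated |= fov.channels[name] == 255
    saturated_fraction = float(np.mean(saturated))

    if any(fov.channels[c].min() == fov.channels[c].max() for c in CHANNEL_ORDER):
        reason = "constant"
    elif background_fraction > tau_bg:
        reason = "border_or_hole"
    elif saturated_fraction > tau_sat:
        reason = "saturation"
    else:
        reason = "ok"
    return QcReport(
        accepted=reason == "ok",
        background_fraction=background_fraction,
        saturated_fraction=saturated_fraction,
        reason=reason,
    )
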