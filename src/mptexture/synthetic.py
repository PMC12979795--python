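"""Synthetic patient-structured three-channel multiphoton cohorts.

Real cryosection images of liver and hepatocellular carcinoma are not
publicly deposited, so this module generates surrogate fields of view whose
channel-wise texture statistics mimic the tissue structures the modality
resolves: a band-limited cellular autofluorescence field with dark
nucleus-like voids (TPEF), sparse curvilinear collagen strands (SHG), and a
cellular baseline with bright lipid-droplet disks (CARS). Class identity
(liver vs. tumor) is carried entirely by the texture parameters — correlation
length and contrast of the cellular field, droplet load, fiber load — with a
per-patient multiplicative random effect shared between a patient's liver and
tumor samples, emulating between-patient biological variation.

The generator is deterministic: one global seed expands to per-patient and
per-FoV seeds through ``numpy.random.SeedSequence`` spawn keys, so any FoV
can be regenerated bit-identically regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import poisson
from skimage.draw import line as _draw_line
from skimage.morphology import disk as _disk_struct

from .fov_io import FovImage, write_fov

#: Nominal acquisition geometry: 152 µm × 302 µm at 1 µm per pixel.
DEFAULT_SHAPE: tuple[int, int] = (152, 302)
DEFAULT_PIXEL_SIZE: float = 1.0


class InvalidSpecError(ValueError):
    """Raised for cohort/tissue specifications that violate their invariants."""


@dataclass(frozen=True)
class TissueParams:
    """Texture parameters of one tissue class for one patient.

    Units: ``cell_scale``, ``droplet_radius_range`` and ``fiber_thickness``
    are in µm; ``droplet_density`` is expected droplets per 10^4 µm^2;
    ``fiber_density`` is expected fibers per FoV; ``cell_contrast`` and
    ``noise_scale`` are dimensionless.
    """

    cell_scale: float
    cell_contrast: float
    droplet_density: float
    droplet_radius_range: tuple[float, float]
    fiber_density: float
    fiber_thickness: float
    noise_scale: float
    class_label: str  # liver | tumor

    def __post_init__(self) -> None:
        if self.class_label not in ("liver", "tumor"):
            raise InvalidSpecError(f"unknown class_label {self.class_label!r}")
        for name in ("cell_scale", "droplet_density", "fiber_density", "fiber_thickness", "noise_scale"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")
        if not 0.0 <= self.cell_contrast <= 1.0:
            raise InvalidSpecError("cell_contrast must lie in [0, 1]")
        rmin, rmax = self.droplet_radius_range
        if rmin < 0 or rmin > rmax:
            raise InvalidSpecError("droplet_radius_range must satisfy 0 <= min <= max")


# Reference class parameter sets at full separation (delta = 1). Liver shows a
# fine cellular texture, frequent lipid droplets (steatosis is common in the
# background liver) and portal-tract collagen; ordinary HCC shows a coarser,
# higher-contrast cellular texture (thick trabeculae), fewer droplets and
# little intratumoral stroma.
LIVER_REFERENCE = TissueParams(
    cell_scale=4.0,
    cell_contrast=0.45,
    droplet_density=15.0,
    droplet_radius_range=(1.0, 3.0),
    fiber_density=12.0,
    fiber_thickness=1.5,
    noise_scale=0.10,
    class_label="liver",
)
TUMOR_REFERENCE = TissueParams(
    cell_scale=7.0,
    cell_contrast=0.65,
    droplet_density=5.0,
    droplet_radius_range=(1.0, 2.0),
    fiber_density=4.0,
    fiber_thickness=2.0,
    noise_scale=0.10,
    class_label="tumor",
)

# Parameters that receive the multiplicative per-patient random effect and
# the delta (class-separation) scaling. All are positive scale parameters.
_SCALED_FIELDS = ("cell_scale", "cell_contrast", "droplet_density", "fiber_density", "fiber_thickness")


@dataclass(frozen=True)
class PatientSpec:
    """Everything needed to regenerate one synthetic patient bit-identically."""

    patient_id: str
    seed: int
    liver_params: TissueParams
    tumor_params: TissueParams
    n_fov_liver: int
    n_fov_tumor: int
    has_border_sample: bool = False

    def __post_init__(self) -> None:
        if self.n_fov_liver < 0 or self.n_fov_tumor < 0:
            raise InvalidSpecError("FoV counts must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Study-level description of a synthetic cohort.

    ``class_separation`` (delta) scales the geometric distance between the
    liver and tumor class means of every texture parameter: delta = 1
    reproduces the reference parameter sets, delta = 0 collapses both classes
    onto their geometric midpoint (identical distributions — the null cohort).
    ``patient_sd`` is the log-normal sigma of the per-patient random effect.
    """

    n_patients: int
    class_separation: float = 1.0
    patient_sd: float = 0.15
    image_shape: tuple[int, int] = DEFAULT_SHAPE
    pixel_size: float = DEFAULT_PIXEL_SIZE
    n_fov_liver: int = 50
    n_fov_tumor: int = 50
    n_border_patients: int = 0
    border_grid: tuple[int, int] = (4, 10)
    boundary_col: int = 5
    liver_template: TissueParams | None = None
    tumor_template: TissueParams | None = None

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise InvalidSpecError("n_patients must be positive")
        if self.class_separation < 0:
            raise InvalidSpecError("class_separation must be >= 0")
        if self.patient_sd < 0:
            raise InvalidSpecError("patient_sd must be >= 0")
        if self.image_shape[0] <= 0 or self.image_shape[1] <= 0:
            raise InvalidSpecError("image_shape must be positive")
        if self.n_border_patients > self.n_patients:
            raise InvalidSpecError("n_border_patients exceeds n_patients")

    def class_means(self) -> tuple[TissueParams, TissueParams]:
        """Liver and tumor class-mean parameters at this separation."""
        if self.liver_template is not None and self.tumor_template is not None:
            liver, tumor = self.liver_template, self.tumor_template
        else:
            liver, tumor = LIVER_REFERENCE, TUMOR_REFERENCE
        return (
            _interpolate_class(liver, tumor, self.class_separation, "liver"),
            _interpolate_class(liver, tumor, self.class_separation, "tumor"),
        )


def _geo_interp(lo: float, hi: float, exponent: float) -> float:
    """Geometric interpolation mid * (hi/lo)^(exponent/2) around the midpoint."""
    if lo <= 0 or hi <= 0:
        # degenerate reference (zero density): fall back to linear scaling
        mid = 0.5 * (lo + hi)
        return mid + exponent * 0.5 * (hi - lo)
    mid = math.sqrt(lo * hi)
    return mid * (hi / lo) ** (exponent / 2.0)


def _interpolate_class(liver: TissueParams, tumor: TissueParams, delta: float, which: str) -> TissueParams:
    sign = -1.0 if which == "liver" else 1.0
    kwargs: dict = {"class_label": which, "noise_scale": 0.5 * (liver.noise_scale + tumor.noise_scale)}
    for name in _SCALED_FIELDS:
        value = _geo_interp(getattr(liver, name), getattr(tumor, name), sign * delta)
        if name == "cell_contrast":
            value = min(value, 1.0)
        kwargs[name] = value
    rmin = _geo_interp(liver.droplet_radius_range[0], tumor.droplet_radius_range[0], sign * delta)
    rmax = _geo_interp(liver.droplet_radius_range[1], tumor.droplet_radius_range[1], sign * delta)
    kwargs["droplet_radius_range"] = (min(rmin, rmax), max(rmin, rmax))
    return TissueParams(**kwargs)


def _patient_seed_sequence(seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index),))


def sample_cohort(spec: CohortSpec, seed: int) -> list[PatientSpec]:
    """Draw per-patient tissue parameters for a cohort.

    Each patient receives one multiplicative log-normal random effect per
    scale parameter, applied to both class means — a patient-level effect
    shared by that patient's liver and tumor samples. Deterministic given
    ``seed``; patient k's parameters do not depend on cohort size.
    """
    liver_mean, tumor_mean = spec.class_means()
    patients: list[PatientSpec] = []
    for i in range(spec.n_patients):
        ss = _patient_seed_sequence(seed, i)
        rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
        factors = {
            name: float(np.exp(rng.normal(0.0, spec.patient_sd))) for name in _SCALED_FIELDS
        }
        radius_factor = float(np.exp(rng.normal(0.0, spec.patient_sd)))

        def _apply(mean: TissueParams) -> TissueParams:
            kwargs = {
                name: min(getattr(mean, name) * factors[name], 1.0)
                if name == "cell_contrast"
                else getattr(mean, name) * factors[name]
                for name in _SCALED_FIELDS
            }
            rmin, rmax = mean.droplet_radius_range
            return replace(
                mean,
                droplet_radius_range=(rmin * radius_factor, rmax * radius_factor),
                **kwargs,
            )

        patients.append(
            PatientSpec(
                patient_id=f"P{i:03d}",
                seed=int(ss.generate_state(1)[0] % (2**31)),
                liver_params=_apply(liver_mean),
                tumor_params=_apply(tumor_mean),
                n_fov_liver=spec.n_fov_liver,
                n_fov_tumor=spec.n_fov_tumor,
                has_border_sample=i >= spec.n_patients - spec.n_border_patients,
            )
        )
    return patients


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _gaussian_field(shape: tuple[int, int], sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary zero-mean unit-variance random field with correlation length
    ~sigma_px, obtained by Gaussian filtering of white noise (wrap boundary
    keeps the field stationary up to the image edge)."""
    noise = rng.standard_normal(shape)
    if sigma_px <= 0:
        return noise
    f = ndimage.gaussian_filter(noise, sigma_px, mode="wrap")
    sd = f.std()
    if sd > 0:
        f = (f - f.mean()) / sd
    return f


def _poisson_count(lam: float, rng: np.random.Generator) -> int:
    """Poisson count via inverse CDF of a single uniform draw.

    Using one uniform and the quantile function makes the count monotone
    non-decreasing in the rate for a fixed random stream, so increasing an
    object density with the same seed yields a superset of objects.
    """
    if lam <= 0:
        rng.uniform()  # keep the stream aligned across parameter settings
        return 0
    u = rng.uniform()
    return int(poisson.ppf(u, lam))


def _stamp_disk(img: np.ndarray, center: tuple[float, float], radius_px: float, value: float) -> None:
    """Set img = max(img, value) inside a disk; operates on a bounding box."""
    h, w = img.shape
    r0 = max(int(math.floor(center[0] - radius_px)), 0)
    r1 = min(int(math.ceil(center[0] + radius_px)) + 1, h)
    c0 = max(int(math.floor(center[1] - radius_px)), 0)
    c1 = min(int(math.ceil(center[1] + radius_px)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.ogrid[r0:r1, c0:c1]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2
    patch = img[r0:r1, c0:c1]
    patch[mask] = np.maximum(patch[mask], value)


def _stamp_disk_multiply(img: np.ndarray, center: tuple[float, float], radius_px: float, factor: float) -> None:
    h, w = img.shape
    r0 = max(int(math.floor(center[0] - radius_px)), 0)
    r1 = min(int(math.ceil(center[0] + radius_px)) + 1, h)
    c0 = max(int(math.floor(center[1] - radius_px)), 0)
    c1 = min(int(math.ceil(center[1] + radius_px)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.ogrid[r0:r1, c0:c1]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2
    img[r0:r1, c0:c1][mask] *= factor


def _render_tpef(params: TissueParams, shape, pixel_size, rng_field, rng_nuclei) -> np.ndarray:
    """Cellular autofluorescence: correlated field plus dark nucleus voids."""
    f = _gaussian_field(shape, params.cell_scale / pixel_size, rng_field)
    tpef = 0.45 + params.cell_contrast * 0.25 * f
    # nucleus-like voids: fixed density ~40 per 10^4 µm^2, radius ~3 µm
    area_um2 = shape[0] * shape[1] * pixel_size**2
    n_nuclei = rng_nuclei.poisson(40.0 * area_um2 / 1e4)
    for _ in range(n_nuclei):
        center = (rng_nuclei.uniform(0, shape[0]), rng_nuclei.uniform(0, shape[1]))
        radius = rng_nuclei.uniform(2.0, 3.5) / pixel_size
        _stamp_disk_multiply(tpef, center, radius, 0.35)
    return tpef


def _render_cars(params: TissueParams, shape, pixel_size, rng_field, rng_drop) -> np.ndarray:
    """Lipid channel: cellular baseline plus bright droplet disks."""
    g = _gaussian_field(shape, max(params.cell_scale * 0.75, 1.0) / pixel_size, rng_field)
    cars = 0.35 + 0.15 * g
    area_um2 = shape[0] * shape[1] * pixel_size**2
    lam = params.droplet_density * area_um2 / 1e4
    n_droplets = _poisson_count(lam, rng_drop)
    rmin, rmax = params.droplet_radius_range
    for _ in range(n_droplets):
        center = (rng_drop.uniform(0, shape[0]), rng_drop.uniform(0, shape[1]))
        radius = rng_drop.uniform(rmin, max(rmax, rmin + 1e-9)) / pixel_size
        amplitude = rng_drop.uniform(0.85, 0.95)
        _stamp_disk(cars, center, max(radius, 0.5), amplitude)
    return cars


def _render_shg(params: TissueParams, shape, pixel_size, rng_fiber) -> np.ndarray:
    """Collagen channel: smoothed random-walk strands on a zero background."""
    h, w = shape
    shg = np.zeros(shape, dtype=np.float64)
    n_fibers = _poisson_count(params.fiber_density, rng_fiber)
    dilate_radius = int(round(params.fiber_thickness / (2.0 * pixel_size)))
    struct = _disk_struct(dilate_radius) if dilate_radius >= 1 else None
    step_px = 3.0 / pixel_size
    for _ in range(n_fibers):
        r = rng_fiber.uniform(0, h)
        c = rng_fiber.uniform(0, w)
        theta = rng_fiber.uniform(0, 2 * math.pi)
        length_um = rng_fiber.uniform(40.0, 160.0)
        amplitude = rng_fiber.uniform(0.55, 0.85)
        n_steps = max(int(length_um / (step_px * pixel_size)), 2)
        kinks = rng_fiber.normal(0.0, 0.25, size=n_steps)
        mask = np.zeros(shape, dtype=bool)
        prev = (int(round(r)), int(round(c)))
        for k in range(n_steps):
            theta += kinks[k]
            r += step_px * math.sin(theta)
            c += step_px * math.cos(theta)
            cur = (int(round(r)), int(round(c)))
            rr, cc = _draw_line(*prev, *cur)
            inside = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            mask[rr[inside], cc[inside]] = True
            prev = cur
        if struct is not None and mask.any():
            mask = ndimage.binary_dilation(mask, structure=struct)
        shg[mask] = np.maximum(shg[mask], amplitude)
    return shg


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)


def render_fov(
    params: TissueParams,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    rng: np.random.Generator | int | np.random.SeedSequence = 0,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    patient_id: str | None = None,
    sample_kind: str | None = None,
    tile: tuple[int, int] | None = None,
) -> FovImage:
    """Render one three-channel FoV from tissue parameters.

    The generator stream is split into independent substreams per structure
    type (cell field, nuclei, CARS baseline, droplets, fibers, noise), so
    changing one density parameter leaves all other structures untouched for
    a fixed seed.
    """
    if shape[0] <= 0 or shape[1] <= 0:
        raise InvalidSpecError("shape must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    subs = rng.spawn(6)
    tpef = _render_tpef(params, shape, pixel_size, subs[0], subs[1])
    cars = _render_cars(params, shape, pixel_size, subs[2], subs[3])
    shg = _render_shg(params, shape, pixel_size, subs[4])
    rng_noise = subs[5]
    channels = {}
    for name, img in (("CARS", cars), ("TPEF", tpef), ("SHG", shg)):
        noisy = img * (1.0 + params.noise_scale * rng_noise.standard_normal(shape))
        channels[name] = _quantize(noisy)
    return FovImage(
        channels=channels,
        patient_id=patient_id,
        sample_kind=sample_kind,
        tile=tile,
        true_label=params.class_label,
        pixel_size=pixel_size,
    )


def render_border_sample(
    liver: TissueParams,
    tumor: TissueParams,
    grid: tuple[int, int],
    boundary_col: int,
    rng: np.random.Generator | int | np.random.SeedSequence = 0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    patient_id: str | None = None,
) -> list[FovImage]:
    """Render a tiled sample whose class flips at ``boundary_col``.

    Tiles with col < boundary_col are liver, the rest tumor; each FoV carries
    its (row, col) grid position and ground-truth label. ``boundary_col`` may
    be 0 (all tumor) or ``cols`` (all liver).
    """
    rows, cols = grid
    if not 0 <= boundary_col <= cols:
        raise InvalidSpecError(f"boundary_col {boundary_col} outside [0, {cols}]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    tile_rngs = rng.spawn(rows * cols)
    fovs = []
    for r in range(rows):
        for c in range(cols):
            params = liver if c < boundary_col else tumor
            fov = render_fov(
                params,
                shape=shape,
                rng=tile_rngs[r * cols + c],
                pixel_size=pixel_size,
                patient_id=patient_id,
                sample_kind="border",
                tile=(r, c),
            )
            fov.true_label = params.class_label
            fovs.append(fov)
    return fovs


# ---------------------------------------------------------------------------
# Cohort-level generation
# ---------------------------------------------------------------------------


def generate_patient_fovs(pspec: PatientSpec, spec: CohortSpec) -> Iterator[FovImage]:
    """Yield all FoVs of one patient (liver sample, tumor sample, optional
    border sample), each rendered from its own spawned seed."""
    base = np.random.SeedSequence(entropy=pspec.seed)
    for class_idx, (kind, params, count) in enumerate(
        (("liver", pspec.liver_params, pspec.n_fov_liver), ("tumor", pspec.tumor_params, pspec.n_fov_tumor))
    ):
        for j in range(count):
            ss = np.random.SeedSequence(entropy=pspec.seed, spawn_key=(class_idx, j))
            fov = render_fov(
                params,
                shape=spec.image_shape,
                rng=np.random.default_rng(ss),
                pixel_size=spec.pixel_size,
                patient_id=pspec.patient_id,
                sample_kind=kind,
                tile=(0, j),
            )
            yield fov
    if pspec.has_border_sample:
        ss = np.random.SeedSequence(entropy=pspec.seed, spawn_key=(2, 0))
        yield from render_border_sample(
            pspec.liver_params,
            pspec.tumor_params,
            grid=spec.border_grid,
            boundary_col=spec.boundary_col,
            rng=np.random.default_rng(ss),
            shape=spec.image_shape,
            pixel_size=spec.pixel_size,
            patient_id=pspec.patient_id,
        )


def generate_cohort(spec: CohortSpec, seed: int) -> Iterator[tuple[PatientSpec, FovImage]]:
    """Yield (patient, FoV) pairs for a whole cohort, in deterministic order."""
    for pspec in sample_cohort(spec, seed):
        for fov in generate_patient_fovs(pspec, spec):
            yield pspec, fov


def write_cohort(spec: CohortSpec, seed: int, out_dir: str | Path) -> pd.DataFrame:
    """Write a cohort to disk as RGB TIFFs plus a manifest CSV.

    Layout: ``<patient>/<sample>/r<row>_c<col>.tif``; the manifest holds one
    row per FoV with patient_id, sample, path, row, col, true_label.
    """
    out_dir = Path(out_dir)
    rows = []
    for pspec, fov in generate_cohort(spec, seed):
        r, c = fov.tile if fov.tile is not None else (0, 0)
        rel = Path(fov.patient_id) / fov.sample_kind / f"r{r}_c{c}.tif"
        write_fov(fov, out_dir / rel)
        rows.append(
            {
                "patient_id": fov.patient_id,
                "sample": fov.sample_kind,
                "path": str(rel),
                "row": r,
                "col": c,
                "true_label": fov.true_label,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
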