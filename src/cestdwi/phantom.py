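"""Digital phantom generation for a two-group CEST/DWI rodent brain-tumor study.

The generator emulates a control vs. X-ray-irradiated glioma study imaged at
three timepoints (days 8, 10 and 17 after implantation) on a small-animal
scanner: a T2-weighted anatomical stack, a single-slice Z-spectrum CEST series
(saturation offsets -4.8 .. +4.8 ppm in 0.3 ppm steps plus an unsaturated
reference frame) and a single-slice three-b-value DWI series, together with
tumor ROI masks and full per-pixel ground truth.

The Z-spectrum generative model is a sum of Lorentzian saturation lines on top
of unity (a steady-state approximation, not Bloch-McConnell integration):

    Z(dw) = 1 - sum_pools A * (G/2)^2 / ((G/2)^2 + (dw - b0 - delta)^2)

Water and semi-solid MT pools are symmetric about 0 ppm and therefore
contribute no MTR asymmetry; all asymmetry comes from solute pools at positive
offsets (creatine guanidinium at +1.8 ppm by default), whose amplitude is
calibrated in closed form to hit a target asymmetry exactly
(:func:`calibrate_pool_amplitude`).

DWI signals follow a mono-exponential decay S(b) = S0 exp(-b * ADC) with
Rician (magnitude) noise; CEST and T2 images carry Gaussian noise.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ioutils import save_nifti, write_json

__all__ = [
    "AcquisitionGeometry",
    "SaturationSchedule",
    "CESTPool",
    "TissueCompartment",
    "CellParams",
    "PhantomSpec",
    "AnimalDayTruth",
    "GroundTruth",
    "GeometryError",
    "InvalidPoolConfigurationError",
    "lorentzian",
    "synthesize_zspectrum",
    "calibrate_pool_amplitude",
    "synthesize_dwi",
    "sample_compartment_pixels",
    "build_study",
    "default_cells",
    "water_pool",
    "mt_pool",
]

CREATINE_PPM = 1.8

# compartment labels in ground-truth maps
LABEL_BACKGROUND = 0
LABEL_NORMAL = 1
LABEL_MARGIN = 2
LABEL_CENTER = 3


class GeometryError(ValueError):
    """Raised when a requested tumor does not fit the field of view."""


class InvalidPoolConfigurationError(ValueError):
    """Raised when a pool set drives the Z-spectrum negative somewhere."""


def _offsets_default() -> np.ndarray:
    # -4.8 .. +4.8 ppm in 0.3 ppm steps -> 33 offsets, symmetric about 0
    return np.round((np.arange(33) - 16) * 0.3, 10)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Matrix sizes and physical geometry shared by all series of one study."""

    fov_mm: float = 32.0
    t2_matrix: int = 256
    cest_dwi_matrix: int = 128
    slice_thickness_mm: float = 1.0
    n_slices_t2: int = 10
    n_slices_cest_dwi: int = 1

    def __post_init__(self) -> None:
        if self.fov_mm <= 0 or self.t2_matrix <= 0 or self.cest_dwi_matrix <= 0:
            raise ValueError("fov and matrix sizes must be positive")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice thickness must be positive")
        if self.t2_matrix % self.cest_dwi_matrix != 0:
            raise ValueError(
                "t2_matrix must be an integer multiple of cest_dwi_matrix "
                f"(got {self.t2_matrix} and {self.cest_dwi_matrix})"
            )

    @property
    def t2_pixel_mm(self) -> float:
        return self.fov_mm / self.t2_matrix

    @property
    def cest_dwi_pixel_mm(self) -> float:
        return self.fov_mm / self.cest_dwi_matrix

    @property
    def downsample_factor(self) -> int:
        return self.t2_matrix // self.cest_dwi_matrix


@dataclass(frozen=True)
class SaturationSchedule:
    """Saturation offset table for one CEST acquisition.

    ``offsets_ppm`` must be strictly increasing and symmetric about 0 ppm so
    that every positive offset has an exactly sampled mirror.
    """

    offsets_ppm: np.ndarray = field(default_factory=_offsets_default)
    b1_uT: float = 3.0
    reference_included: bool = True

    def __post_init__(self) -> None:
        off = np.asarray(self.offsets_ppm, dtype=float)
        object.__setattr__(self, "offsets_ppm", off)
        if off.ndim != 1 or off.size < 3:
            raise ValueError("offsets_ppm must be a 1-d vector of >= 3 offsets")
        if not np.all(np.diff(off) > 0):
            raise ValueError("offsets_ppm must be strictly increasing")
        if not np.allclose(off + off[::-1], 0.0, atol=1e-9):
            raise ValueError("offsets_ppm must be symmetric about 0")

    @property
    def positive_offsets(self) -> np.ndarray:
        return self.offsets_ppm[self.offsets_ppm > 0]


@dataclass(frozen=True)
class CESTPool:
    """One Lorentzian saturation line (water, MT background, or solute)."""

    delta_ppm: float
    amplitude: float
    fwhm_ppm: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude < 1.0:
            raise ValueError("amplitude must lie in [0, 1)")
        if self.fwhm_ppm <= 0:
            raise ValueError("fwhm_ppm must be positive")


def water_pool(amplitude: float = 0.8, fwhm_ppm: float = 1.4) -> CESTPool:
    """Direct water saturation line, centered at 0 ppm."""
    return CESTPool(delta_ppm=0.0, amplitude=amplitude, fwhm_ppm=fwhm_ppm)


def mt_pool(amplitude: float = 0.1, fwhm_ppm: float = 20.0) -> CESTPool:
    """Broad symmetric semi-solid magnetization-transfer background."""
    return CESTPool(delta_ppm=0.0, amplitude=amplitude, fwhm_ppm=fwhm_ppm)


@dataclass(frozen=True)
class TissueCompartment:
    """Generative description of one tissue class on the CEST/DWI slice."""

    label: str  # tumor_center | tumor_margin | normal | background
    adc: float  # mm^2/s
    s0_t2: float
    pools: tuple[CESTPool, ...] = ()
    b0_shift_ppm: float = 0.0
    pixel_noise_sd: float = 0.0
    mtr_adc_corr: float = 0.0

    def __post_init__(self) -> None:
        if self.adc <= 0:
            raise ValueError("adc must be positive")
        if abs(self.mtr_adc_corr) > 1:
            raise ValueError("mtr_adc_corr must lie in [-1, 1]")


def lorentzian(x: np.ndarray | float, amplitude: float, fwhm: float) -> np.ndarray:
    """Lorentzian line A * (G/2)^2 / ((G/2)^2 + x^2) with peak A at x = 0."""
    hw2 = (fwhm / 2.0) ** 2
    return amplitude * hw2 / (hw2 + np.square(x))


def synthesize_zspectrum(
    pools: Sequence[CESTPool],
    schedule: SaturationSchedule | None = None,
    b0_shift_ppm: float = 0.0,
) -> np.ndarray:
    """Evaluate the Lorentzian-sum Z-spectrum on the scheduled offsets.

    Returns the normalized saturation signal Z(dw) in [0, 1] at every offset.
    A local field error ``b0_shift_ppm`` translates every line by the same
    amount (the apparent water center moves to +b0).
    """
    if schedule is None:
        schedule = SaturationSchedule()
    x = schedule.offsets_ppm - b0_shift_ppm
    z = np.ones_like(x)
    for pool in pools:
        z = z - lorentzian(x - pool.delta_ppm, pool.amplitude, pool.fwhm_ppm)
    if np.any(z < 0):
        bad = schedule.offsets_ppm[np.argmin(z)]
        raise InvalidPoolConfigurationError(
            f"pool configuration drives Z below 0 at {bad:+.2f} ppm"
        )
    return z


def calibrate_pool_amplitude(
    target_mtr_pct: float, delta_ppm: float, fwhm_ppm: float
) -> float:
    """Solute amplitude whose MTR asymmetry at its own center equals the target.

    For a single solute Lorentzian at +delta over a symmetric background, the
    asymmetry at +delta is A * (1 - t) with tail factor
    t = (G/2)^2 / ((G/2)^2 + (2 delta)^2), hence A = (target/100) / (1 - t).
    """
    if delta_ppm == 0:
        raise ValueError("no asymmetry is possible for a pool at 0 ppm")
    if not 0 < target_mtr_pct < 100:
        raise ValueError("target_mtr_pct must lie in (0, 100)")
    if fwhm_ppm <= 0:
        raise ValueError("fwhm_ppm must be positive")
    hw2 = (fwhm_ppm / 2.0) ** 2
    tail = hw2 / (hw2 + (2.0 * delta_ppm) ** 2)
    return (target_mtr_pct / 100.0) / (1.0 - tail)


def synthesize_dwi(
    adc: float,
    s0: float,
    b_values: Sequence[float],
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Mono-exponential DWI signals S(b) = s0 exp(-b adc), Rician-corrupted.

    With ``noise_sd`` > 0 the magnitude of (S + n1 + i n2) is returned with
    n1, n2 ~ N(0, noise_sd^2); noise_sd == 0 gives the exact decay.
    """
    b = np.asarray(b_values, dtype=float)
    if adc <= 0:
        raise ValueError("adc must be positive")
    if b.size < 1 or np.any(b < 0) or b[0] != 0:
        raise ValueError("b_values must be non-negative with first element 0")
    s = s0 * np.exp(-b * adc)
    if noise_sd > 0:
        gen = np.random.default_rng(rng)
        n1 = gen.normal(0.0, noise_sd, size=s.shape)
        n2 = gen.normal(0.0, noise_sd, size=s.shape)
        s = np.hypot(s + n1, n2)
    return s


# ---------------------------------------------------------------------------
# Study-level specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellParams:
    """Generative parameters for one (group, day) cell of the study design.

    ADC values are in mm^2/s; MTR targets in percent. ``*_contrast`` is the
    center-minus-margin difference of the compartment means (area-weighted so
    the tumor mean stays at ``*_mean``). ``*_sd_pixel`` is the within-
    compartment per-pixel SD, ``*_sd_animal`` the between-animal SD of the
    compartment means, and ``rho`` the within-compartment correlation between
    the per-pixel ADC and MTR perturbations.
    """

    volume_mm3: float
    volume_sd: float
    adc_mean: float
    adc_contrast: float
    mtr_mean_pct: float
    mtr_contrast_pct: float
    adc_sd_pixel: float
    mtr_sd_pixel_pct: float
    adc_sd_animal: float
    mtr_sd_animal_pct: float
    rho: float

    def __post_init__(self) -> None:
        if self.volume_mm3 <= 0 or self.adc_mean <= 0:
            raise ValueError("volume and adc_mean must be positive")
        if abs(self.rho) > 1:
            raise ValueError("rho must lie in [-1, 1]")


def default_cells() -> dict[tuple[str, int], CellParams]:
    """Default (group, day) parameters emulating the published study.

    Tumor-mean volumes, ADC and creatine-MTR targets, between-animal and
    per-pixel dispersions follow the group trajectories of the original
    experiment; the day-17 control cell carries a center/margin contrast
    (edematous high-ADC, creatine-poor center) and a positive within-
    compartment ADC-MTR coupling, all other cells are spatially uniform with
    negative coupling.
    """
    c = {
        ("control", 8): CellParams(26.3, 20.8, 0.6e-3, 0.0, 5.6, 0.0,
                                   0.06e-3, 1.9, 0.06e-3, 1.3, -0.5),
        ("control", 10): CellParams(51.3, 36.2, 0.7e-3, 0.0, 5.6, 0.0,
                                    0.08e-3, 1.8, 0.08e-3, 0.6, -0.8),
        ("control", 17): CellParams(152.2, 55.0, 0.8e-3, 0.2e-3, 5.9, -1.5,
                                    0.14e-3, 2.3, 0.07e-3, 0.5, 0.8),
        ("irradiated", 8): CellParams(18.6, 6.9, 0.6e-3, 0.0, 6.4, 0.0,
                                      0.05e-3, 2.0, 0.05e-3, 1.6, -0.5),
        ("irradiated", 10): CellParams(23.0, 9.0, 0.6e-3, 0.0, 4.3, 0.0,
                                       0.06e-3, 1.9, 0.03e-3, 0.6, -0.8),
        ("irradiated", 17): CellParams(27.3, 7.3, 0.7e-3, 0.0, 5.0, 0.0,
                                       0.11e-3, 1.5, 0.03e-3, 0.3, -0.8),
    }
    return c


@dataclass
class PhantomSpec:
    """Complete generative description of a synthetic two-group study."""

    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    schedule: SaturationSchedule = field(default_factory=SaturationSchedule)
    groups: tuple[str, ...] = ("control", "irradiated")
    days: tuple[int, ...] = (8, 10, 17)
    n_animals_per_group: int = 6
    cells: dict[tuple[str, int], CellParams] = field(default_factory=default_cells)
    seed: int = 0

    # tumor layout
    tumor_slices: int = 4
    tumor_center_mm: tuple[float, float] = (0.0, 6.0)  # in-plane, from FOV center
    center_area_fraction: float = 0.36  # tumor-center disk area / tumor area
    brain_radius_mm: float = 12.0

    # normal tissue and signal levels
    normal_adc: float = 0.75e-3
    normal_mtr_pct: float = 4.0
    normal_adc_sd: float = 0.02e-3
    normal_mtr_sd_pct: float = 0.5
    solute_delta_ppm: float = CREATINE_PPM
    solute_fwhm_ppm: float = 1.0
    water_amplitude: float = 0.8
    water_fwhm_ppm: float = 1.4
    mt_amplitude: float = 0.1
    mt_fwhm_ppm: float = 20.0

    # signal scales and noise
    s0_cest: float = 1000.0
    s0_dwi: float = 1000.0
    s0_t2_tumor: float = 1500.0
    s0_t2_normal: float = 1000.0
    s0_background: float = 30.0
    cest_noise_sd: float = 2.0
    dwi_noise_sd: float = 10.0
    t2_noise_sd: float = 20.0
    b_values: tuple[float, ...] = (0.0, 1000.0, 2000.0)
    b0_range_ppm: float = 0.1  # per-animal field error ~ U(-range, +range)

    def validate(self) -> None:
        for g in self.groups:
            for d in self.days:
                if (g, d) not in self.cells:
                    raise ValueError(f"no CellParams for cell ({g}, {d})")
        days = sorted(self.days)
        if "control" in self.groups and len(days) > 1:
            vols = [self.cells[("control", d)].volume_mm3 for d in days]
            if not all(b > a for a, b in zip(vols, vols[1:])):
                raise ValueError("control tumor volume must increase with day")
        if {"control", "irradiated"} <= set(self.groups) and len(days) > 1:
            cg = (self.cells[("control", days[-1])].volume_mm3
                  - self.cells[("control", days[0])].volume_mm3)
            ig = (self.cells[("irradiated", days[-1])].volume_mm3
                  - self.cells[("irradiated", days[0])].volume_mm3)
            if cg > 0 and ig / cg > 0.25:
                raise ValueError(
                    "irradiated-group growth must stay small relative to control"
                )
        if self.tumor_slices > self.geometry.n_slices_t2:
            raise GeometryError("tumor spans more slices than the T2 stack")
        # worst-case radius must fit the FOV
        vmax = max(c.volume_mm3 + 3 * c.volume_sd for c in self.cells.values())
        rmax = math.sqrt(vmax / self.tumor_slices / math.pi)
        cx, cy = self.tumor_center_mm
        if math.hypot(cx, cy) + rmax > self.geometry.fov_mm / 2.0:
            raise GeometryError("tumor may not fit inside the field of view")

    def background_pools(self) -> tuple[CESTPool, ...]:
        return (water_pool(self.water_amplitude, self.water_fwhm_ppm),
                mt_pool(self.mt_amplitude, self.mt_fwhm_ppm))

    def to_json(self, path: str | Path) -> None:
        write_json(Path(path), _spec_to_dict(self))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        with open(path) as fh:
            return _spec_from_dict(json.load(fh))


def _spec_to_dict(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["geometry"] = dataclasses.asdict(spec.geometry)
    d["schedule"] = {
        "offsets_ppm": spec.schedule.offsets_ppm.tolist(),
        "b1_uT": spec.schedule.b1_uT,
        "reference_included": spec.schedule.reference_included,
    }
    d["cells"] = {
        f"{g}:{day}": dataclasses.asdict(cp) for (g, day), cp in spec.cells.items()
    }
    return d


def _spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    d["geometry"] = AcquisitionGeometry(**d["geometry"])
    sched = d["schedule"]
    d["schedule"] = SaturationSchedule(
        offsets_ppm=np.asarray(sched["offsets_ppm"], dtype=float),
        b1_uT=sched.get("b1_uT", 3.0),
        reference_included=sched.get("reference_included", True),
    )
    d["cells"] = {
        (k.split(":")[0], int(k.split(":")[1])): CellParams(**v)
        for k, v in d["cells"].items()
    }
    for key in ("groups", "days", "tumor_center_mm", "b_values"):
        if key in d:
            d[key] = tuple(d[key])
    return PhantomSpec(**d)


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class AnimalDayTruth:
    """Per-acquisition ground truth on the CEST/DWI grid."""

    animal: str
    group: str
    day: int
    adc_map: np.ndarray          # mm^2/s, NaN outside tissue
    mtr_map: np.ndarray          # percent, NaN outside tissue
    label_map: np.ndarray        # int compartment labels
    b0_shift_ppm: float
    volume_mm3: float            # from the T2-grid mask, pixel count x voxel
    n_tumor_pixels: int          # on the CEST/DWI grid


@dataclass
class GroundTruth:
    """All per-acquisition truths plus the study manifest table."""

    records: dict[tuple[str, int, str], AnimalDayTruth]
    manifest: pd.DataFrame


def sample_compartment_pixels(
    n: int,
    adc_mean: float,
    mtr_mean_pct: float,
    adc_sd: float,
    mtr_sd_pct: float,
    rho: float,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw correlated per-pixel (ADC, MTR) pairs for one compartment.

    The pair is bivariate normal with the given marginal SDs and correlation
    ``rho``; ADC draws are clipped to stay positive and MTR targets to (0, 50)
    so the Lorentzian amplitude calibration stays well defined.
    """
    gen = np.random.default_rng(rng)
    cov = [[adc_sd**2, rho * adc_sd * mtr_sd_pct],
           [rho * adc_sd * mtr_sd_pct, mtr_sd_pct**2]]
    draws = gen.multivariate_normal([adc_mean, mtr_mean_pct], cov, size=n,
                                    method="cholesky")
    adc = np.clip(draws[:, 0], 1e-5, None)
    mtr = np.clip(draws[:, 1], 0.1, 50.0)
    return adc, mtr


# ---------------------------------------------------------------------------
# build_study
# ---------------------------------------------------------------------------


def _disk_mask(matrix: int, pixel_mm: float, center_mm: tuple[float, float],
               radius_mm: float) -> np.ndarray:
    """Boolean disk on a square grid, pixel-center convention."""
    coord = (np.arange(matrix) + 0.5) * pixel_mm - matrix * pixel_mm / 2.0
    yy, xx = np.meshgrid(coord, coord, indexing="ij")
    cy, cx = center_mm[1], center_mm[0]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_mm**2


def _label_map(spec: PhantomSpec, radius_mm: float) -> np.ndarray:
    g = spec.geometry
    m = g.cest_dwi_matrix
    pix = g.cest_dwi_pixel_mm
    labels = np.full((m, m), LABEL_BACKGROUND, dtype=np.int16)
    labels[_disk_mask(m, pix, (0.0, 0.0), spec.brain_radius_mm)] = LABEL_NORMAL
    tumor = _disk_mask(m, pix, spec.tumor_center_mm, radius_mm)
    r_center = radius_mm * math.sqrt(spec.center_area_fraction)
    center = _disk_mask(m, pix, spec.tumor_center_mm, r_center)
    labels[tumor] = LABEL_MARGIN
    labels[tumor & center] = LABEL_CENTER
    return labels


def _compartment_means(mean: float, contrast: float, w_center: float) -> tuple[float, float]:
    """Center/margin means with area-weighted tumor mean preserved."""
    w_margin = 1.0 - w_center
    return mean + w_margin * contrast, mean - w_center * contrast


def build_study(spec: PhantomSpec, out_dir: str | Path) -> GroundTruth:
    """Generate and write a full synthetic study; return its ground truth.

    For every animal x day the writer emits a T2 stack, a 4-D CEST series
    (reference frame first) with an offset sidecar, a 4-D DWI series with a
    b-value sidecar, the T2-grid tumor mask, and ground-truth ADC / MTR /
    label maps, plus one ``manifest.csv`` for the study. All randomness flows
    from ``spec.seed`` through a hierarchical stream (study -> animal ->
    day -> channel), so rebuilding the same spec is bit-identical.
    """
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = spec.geometry
    offsets = spec.schedule.offsets_ppm
    bvals = np.asarray(spec.b_values, dtype=float)
    days = tuple(spec.days)

    root = np.random.SeedSequence(spec.seed)
    animal_seeds = root.spawn(len(spec.groups) * spec.n_animals_per_group)

    records: dict[tuple[str, int, str], AnimalDayTruth] = {}
    rows = []
    idx = 0
    for group in spec.groups:
        for a in range(spec.n_animals_per_group):
            animal = f"{group[:4]}{a + 1:02d}"
            ss = animal_seeds[idx]
            idx += 1
            arng = np.random.default_rng(ss)
            # animal-level latent effects, shared across days
            z_vol = arng.standard_normal()
            z_adc = arng.standard_normal()
            z_mtr = arng.standard_normal()
            b0 = arng.uniform(-spec.b0_range_ppm, spec.b0_range_ppm)
            day_seeds = ss.spawn(len(days))
            for day, dss in zip(days, day_seeds):
                truth, paths = _build_animal_day(
                    spec, group, day, animal, z_vol, z_adc, z_mtr, b0,
                    dss, out, g, offsets, bvals,
                )
                records[(group, day, animal)] = truth
                rows.append({
                    "animal": animal, "group": group, "day": day,
                    **paths,
                    "true_volume_mm3": truth.volume_mm3,
                    "b0_shift_ppm": truth.b0_shift_ppm,
                    "n_tumor_pixels": truth.n_tumor_pixels,
                })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    spec.to_json(out / "phantom_spec.json")
    return GroundTruth(records=records, manifest=manifest)


def _build_animal_day(spec, group, day, animal, z_vol, z_adc, z_mtr, b0,
                      day_seed, out, g, offsets, bvals):
    cell = spec.cells[(group, day)]
    volume = max(cell.volume_mm3 + z_vol * cell.volume_sd, 2.0)
    radius = math.sqrt(volume / spec.tumor_slices / math.pi)
    cx, cy = spec.tumor_center_mm
    if math.hypot(cx, cy) + radius > g.fov_mm / 2.0:
        raise GeometryError(
            f"tumor radius {radius:.1f} mm does not fit the FOV for {animal} day {day}"
        )

    labels = _label_map(spec, radius)
    m = g.cest_dwi_matrix
    factor = g.downsample_factor
    tumor128 = labels >= LABEL_MARGIN
    n_tumor = int(tumor128.sum())

    # T2-grid mask: 2x2 block upsampling of the CEST-grid tumor mask, stacked
    # over the tumor slices centred on the CEST slice.
    mask_slice = np.kron(tumor128, np.ones((factor, factor), dtype=np.uint8))
    mask_t2 = np.zeros((g.t2_matrix, g.t2_matrix, g.n_slices_t2), dtype=np.uint8)
    central = g.n_slices_t2 // 2
    lo = central - spec.tumor_slices // 2
    for s in range(lo, lo + spec.tumor_slices):
        mask_t2[:, :, s] = mask_slice
    pixel_area = g.t2_pixel_mm**2
    volume_true = float(mask_t2.sum() * pixel_area * g.slice_thickness_mm)

    # compartment means with animal effects
    w_c = spec.center_area_fraction
    adc_c, adc_m = _compartment_means(cell.adc_mean + z_adc * cell.adc_sd_animal,
                                      cell.adc_contrast, w_c)
    mtr_c, mtr_m = _compartment_means(cell.mtr_mean_pct + z_mtr * cell.mtr_sd_animal_pct,
                                      cell.mtr_contrast_pct, w_c)

    # per-pixel ground truth
    ch = day_seed.spawn(4)
    pix_rng = np.random.default_rng(ch[0])
    adc_map = np.full((m, m), np.nan)
    mtr_map = np.full((m, m), np.nan)
    comp_params = {
        LABEL_CENTER: (adc_c, mtr_c, cell.adc_sd_pixel, cell.mtr_sd_pixel_pct, cell.rho),
        LABEL_MARGIN: (adc_m, mtr_m, cell.adc_sd_pixel, cell.mtr_sd_pixel_pct, cell.rho),
        LABEL_NORMAL: (spec.normal_adc, spec.normal_mtr_pct,
                       spec.normal_adc_sd, spec.normal_mtr_sd_pct, 0.0),
    }
    for lab, (am, mm_, asd, msd, rho) in comp_params.items():
        sel = labels == lab
        n = int(sel.sum())
        if n == 0:
            continue
        adc_px, mtr_px = sample_compartment_pixels(n, am, mm_, asd, msd, rho, pix_rng)
        adc_map[sel] = adc_px
        mtr_map[sel] = mtr_px

    # CEST series: reference frame first, then one frame per offset
    tissue = labels >= LABEL_NORMAL
    amp = np.zeros((m, m))
    amp[tissue] = _calibrate_vec(mtr_map[tissue], spec.solute_delta_ppm,
                                 spec.solute_fwhm_ppm)
    base = np.ones_like(offsets)
    for pool in spec.background_pools():
        base = base - lorentzian(offsets - b0 - pool.delta_ppm,
                                 pool.amplitude, pool.fwhm_ppm)
    solute_line = lorentzian(offsets - b0 - spec.solute_delta_ppm, 1.0,
                             spec.solute_fwhm_ppm)
    z = np.ones((m, m, offsets.size))
    z[tissue] = base[None, :] - amp[tissue, None] * solute_line[None, :]

    s0_cest = np.where(tissue, spec.s0_cest, spec.s0_background)
    cest_rng = np.random.default_rng(ch[1])
    cest = np.empty((m, m, 1, offsets.size + 1), dtype=np.float64)
    cest[:, :, 0, 0] = s0_cest
    cest[:, :, 0, 1:] = s0_cest[:, :, None] * z
    if spec.cest_noise_sd > 0:
        cest += cest_rng.normal(0.0, spec.cest_noise_sd, size=cest.shape)

    # DWI series (Rician)
    s0_dwi = np.where(tissue, spec.s0_dwi, spec.s0_background)
    adc_for_decay = np.where(tissue, adc_map, 2.0e-3)  # free water outside
    dwi_rng = np.random.default_rng(ch[2])
    decay = s0_dwi[:, :, None] * np.exp(-adc_for_decay[:, :, None] * bvals[None, None, :])
    if spec.dwi_noise_sd > 0:
        n1 = dwi_rng.normal(0.0, spec.dwi_noise_sd, size=decay.shape)
        n2 = dwi_rng.normal(0.0, spec.dwi_noise_sd, size=decay.shape)
        decay = np.hypot(decay + n1, n2)
    dwi = decay[:, :, None, :]

    # T2 stack
    t2_rng = np.random.default_rng(ch[3])
    brain256 = _disk_mask(g.t2_matrix, g.t2_pixel_mm, (0.0, 0.0), spec.brain_radius_mm)
    t2_slice = np.where(brain256, spec.s0_t2_normal, spec.s0_background)
    t2 = np.repeat(t2_slice[:, :, None], g.n_slices_t2, axis=2).astype(float)
    t2[mask_t2 > 0] = spec.s0_t2_tumor
    if spec.t2_noise_sd > 0:
        t2 += t2_rng.normal(0.0, spec.t2_noise_sd, size=t2.shape)

    # write everything
    stem = f"{animal}_day{day:02d}"
    pix_c = g.cest_dwi_pixel_mm
    pix_t = g.t2_pixel_mm
    paths = {}
    paths["t2"] = str(save_nifti(t2, out / f"{stem}_t2.nii.gz", pix_t,
                                 g.slice_thickness_mm))
    paths["mask_t2"] = str(save_nifti(mask_t2, out / f"{stem}_mask_t2.nii.gz",
                                      pix_t, g.slice_thickness_mm))
    paths["cest"] = str(save_nifti(cest, out / f"{stem}_cest.nii.gz", pix_c,
                                   g.slice_thickness_mm))
    paths["dwi"] = str(save_nifti(dwi, out / f"{stem}_dwi.nii.gz", pix_c,
                                  g.slice_thickness_mm))
    paths["adc_true"] = str(save_nifti(np.nan_to_num(adc_map, nan=0.0),
                                       out / f"{stem}_adc_true.nii.gz", pix_c,
                                       g.slice_thickness_mm))
    paths["mtr_true"] = str(save_nifti(np.nan_to_num(mtr_map, nan=0.0),
                                       out / f"{stem}_mtr_true.nii.gz", pix_c,
                                       g.slice_thickness_mm))
    paths["labels"] = str(save_nifti(labels.astype(np.int16),
                                     out / f"{stem}_labels.nii.gz", pix_c,
                                     g.slice_thickness_mm))
    cest_sidecar = {
        "offsets_ppm": offsets.tolist(),
        "reference_index": 0,
        "b1_uT": spec.schedule.b1_uT,
        "fov_mm": g.fov_mm,
        "matrix": m,
        "seed": spec.seed,
    }
    dwi_sidecar = {
        "bvalues_s_per_mm2": bvals.tolist(),
        "fov_mm": g.fov_mm,
        "matrix": m,
        "seed": spec.seed,
    }
    paths["cest_sidecar"] = str(write_json(out / f"{stem}_cest.json", cest_sidecar))
    paths["dwi_sidecar"] = str(write_json(out / f"{stem}_dwi.json", dwi_sidecar))

    truth = AnimalDayTruth(
        animal=animal, group=group, day=day,
        adc_map=adc_map, mtr_map=mtr_map, label_map=labels,
        b0_shift_ppm=b0, volume_mm3=volume_true, n_tumor_pixels=n_tumor,
    )
    return truth, paths


def _calibrate_vec(target_pct: np.ndarray, delta: float, fwhm: float) -> np.ndarray:
    hw2 = (fwhm / 2.0) ** 2
    tail = hw2 / (hw2 + (2.0 * delta) ** 2)
    return (np.asarray(target_pct) / 100.0) / (1.0 - tail)
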