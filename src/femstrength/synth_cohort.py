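"""Synthetic QCT volumes, cohorts, and projected DXA measurements.

The restricted population and astronaut scans behind the hip-strength
standards cannot be redistributed, so this module generates stand-ins with
the statistical structure the downstream analysis assumes: a parametric
proximal femur voxelised into an uncalibrated Hounsfield-unit volume with an
in-field calibration phantom, cohort demographics drawn from published
summary statistics, a multiplicative spaceflight bone-loss effect, and a
projected areal BMD with T-score.

Everything here is synthetic by construction; the femur is a union of simple
solids (head sphere, angled neck cylinder, vertical shaft cylinder) with a
uniform cortical shell, not a statistical shape model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

__all__ = [
    "FemurGeometry",
    "SubjectParams",
    "ScannerModel",
    "QCTVolume",
    "DXAMeasure",
    "CohortSpec",
    "COHORT_SPECS",
    "DEFAULT_ROD_DENSITIES",
    "DEFAULT_TSCORE_REF",
    "generate_volume",
    "generate_cohort",
    "apply_flight_effect",
    "project_dxa",
]

# Calibration-phantom rod nominal densities, mg/cc hydroxyapatite.
DEFAULT_ROD_DENSITIES = (0.0, 75.0, 150.0)

# Young-adult total-hip reference used for T-scores (g/cm^2).  The reference
# population behind clinical T-scores is manufacturer data we do not have;
# these placeholders are pinned to the synthetic generator's young-cohort
# projection at the default demo voxel size, so astronaut-like subjects land
# near T ~ +1 and fractured elderly near T ~ -2, mirroring the clinical
# structure the operating bands assume.  Configurable everywhere it is used.
DEFAULT_TSCORE_REF = (1.55, 0.13)


class DegenerateGeometryError(ValueError):
    """Voxel size too coarse for the requested femur geometry."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FemurGeometry:
    """Parametric proximal femur: sphere head, angled cylindrical neck,
    vertical cylindrical shaft, uniform cortical shell.  All lengths mm,
    angle degrees."""

    head_radius: float = 24.0
    neck_radius: float = 16.0
    neck_length: float = 35.0
    neck_shaft_angle: float = 125.0
    shaft_radius: float = 15.0
    shaft_length: float = 70.0
    cortical_thickness: float = 3.0

    def __post_init__(self) -> None:
        for name in ("head_radius", "neck_radius", "neck_length",
                     "shaft_radius", "shaft_length", "cortical_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 90.0 < self.neck_shaft_angle < 160.0:
            raise ValueError("neck_shaft_angle must lie in (90, 160) degrees")
        if self.cortical_thickness >= self.neck_radius:
            raise ValueError("cortical_thickness must be < neck_radius")


@dataclass(frozen=True)
class SubjectParams:
    """One synthetic subject: demographics, femur geometry, compartment
    densities (g/cm^3 mineral-equivalent), scanner, optional flight time."""

    subject_id: str
    age: float
    sex: str
    height: float
    weight: float
    geometry: FemurGeometry
    cortical_density: float
    trabecular_density: float
    scanner_id: str = "scanner-0"
    flight_duration: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.trabecular_density < self.cortical_density:
            raise ValueError(
                "require 0 < trabecular_density < cortical_density"
            )
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")


@dataclass(frozen=True)
class ScannerModel:
    """Forward CT model: HU = hu_slope * density(mg/cc) + hu_intercept + noise."""

    scanner_id: str = "scanner-0"
    hu_slope: float = 0.8
    hu_intercept: float = 10.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.hu_slope <= 0:
            raise ValueError("hu_slope must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class QCTVolume:
    """3D voxel volume of HU (uncalibrated) or mg/cc equivalent density
    (calibrated), with spacing, phantom ROIs, and generator metadata."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    calibrated: bool = False
    phantom_rois: list[tuple[np.ndarray, float]] = field(default_factory=list)
    scanner_id: str = "scanner-0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be > 0 on all axes")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def copy(self) -> "QCTVolume":
        return QCTVolume(
            grid=self.grid.copy(),
            spacing=self.spacing,
            calibrated=self.calibrated,
            phantom_rois=[(m.copy(), d) for m, d in self.phantom_rois],
            scanner_id=self.scanner_id,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class DXAMeasure:
    """Projected areal BMD (g/cm^2) and its T-score against a young-adult
    reference; scan_day is days relative to launch (<0) or return (>0)."""

    aBMD: float
    t_score: float
    scan_day: float = 0.0

    def __post_init__(self) -> None:
        if self.aBMD < 0:
            raise ValueError("aBMD must be >= 0")


# ---------------------------------------------------------------------------
# Cohort specifications (mean, SD, (low, high) truncation range)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    name: str
    sex: str  # "male", "female", or "mixed"
    age: tuple[float, float, tuple[float, float]]
    height: tuple[float, float, tuple[float, float]]
    weight: tuple[float, float, tuple[float, float]]
    # compartment densities in g/cm^3 mineral-equivalent
    cortical_density: tuple[float, float, tuple[float, float]] = (
        0.85, 0.08, (0.55, 1.10))
    trabecular_density: tuple[float, float, tuple[float, float]] = (
        0.18, 0.04, (0.05, 0.35))
    density_shift: float = 0.0  # multiplicative shift, e.g. -0.15 for fractured
    flight_duration: Optional[tuple[float, float, tuple[float, float]]] = None


# Published cohort summaries: elderly Icelandic (AGES) fractured /
# non-fractured males, age-stratified Rochester (Mayo) males / females, and
# the 8-astronaut cohort.  Format mean, SD, (range).  Fractured cases carry a
# downward compartment-density shift so their load-capacity distribution sits
# below the non-fractured one.
COHORT_SPECS: dict[str, CohortSpec] = {
    "AGES_fractured": CohortSpec(
        name="AGES_fractured", sex="male",
        age=(80.3, 5.7, (71.0, 93.0)),
        height=(175.1, 5.5, (159.2, 187.1)),
        weight=(80.1, 14.4, (50.3, 114.0)),
        density_shift=-0.15,
    ),
    "AGES_nonfractured": CohortSpec(
        name="AGES_nonfractured", sex="male",
        age=(79.6, 5.2, (70.0, 90.0)),
        height=(174.9, 6.7, (162.4, 190.5)),
        weight=(82.6, 14.8, (52.4, 135.0)),
    ),
    "Mayo_male": CohortSpec(
        name="Mayo_male", sex="male",
        age=(59.9, 16.6, (28.0, 90.0)),
        height=(176.3, 7.2, (157.0, 195.4)),
        weight=(90.2, 16.5, (53.0, 134.0)),
    ),
    "Mayo_female": CohortSpec(
        name="Mayo_female", sex="female",
        age=(60.9, 14.5, (27.0, 90.0)),
        height=(162.3, 6.1, (148.5, 179.2)),
        weight=(74.4, 15.4, (51.0, 128.5)),
    ),
    "astronaut": CohortSpec(
        name="astronaut", sex="mixed",
        age=(46.0, 5.0, (38.0, 53.0)),
        height=(176.0, 5.0, (168.0, 180.0)),
        weight=(72.0, 12.0, (59.0, 88.0)),
        cortical_density=(0.92, 0.06, (0.75, 1.10)),
        trabecular_density=(0.22, 0.03, (0.12, 0.32)),
        flight_duration=(154.0, 19.0, (125.0, 169.0)),
    ),
}


def _draw_truncnorm(rng: np.random.Generator, mean: float, sd: float,
                    bounds: tuple[float, float], size: int) -> np.ndarray:
    if sd <= 0:
        return np.full(size, mean)
    a = (bounds[0] - mean) / sd
    b = (bounds[1] - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                         random_state=rng)


# ---------------------------------------------------------------------------
# Volume generation
# ---------------------------------------------------------------------------

def _femur_mask(geom: FemurGeometry, xx, yy, zz) -> np.ndarray:
    """Boolean mask of the parametric femur on the coordinate grids (mm)."""
    # Shaft: vertical cylinder from z=0 to shaft_length, axis at (0, 0).
    shaft = (
        (xx ** 2 + yy ** 2 <= geom.shaft_radius ** 2)
        & (zz >= 0.0) & (zz <= geom.shaft_length)
    )
    # Neck: cylinder from the shaft top going supero-medially (+x) at
    # (180 - neck_shaft_angle) degrees from vertical.
    tilt = np.deg2rad(180.0 - geom.neck_shaft_angle)
    nd = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
    base = np.array([0.0, 0.0, geom.shaft_length - geom.shaft_radius])
    px, py, pz = xx - base[0], yy - base[1], zz - base[2]
    t = px * nd[0] + py * nd[1] + pz * nd[2]
    d2 = (px - t * nd[0]) ** 2 + (py - t * nd[1]) ** 2 + (pz - t * nd[2]) ** 2
    neck = (t >= 0.0) & (t <= geom.neck_length) & (d2 <= geom.neck_radius ** 2)
    # Head: sphere at the end of the neck axis.
    hc = base + geom.neck_length * nd
    head = ((xx - hc[0]) ** 2 + (yy - hc[1]) ** 2
            + (zz - hc[2]) ** 2) <= geom.head_radius ** 2
    return shaft | neck | head, hc


def generate_volume(params: SubjectParams, scanner: ScannerModel,
                    voxel_mm: float = 3.0,
                    seed: int | np.random.Generator = 0,
                    rod_densities: Sequence[float] = DEFAULT_ROD_DENSITIES,
                    rod_radius: float | None = None) -> QCTVolume:
    """Voxelise the subject's femur plus an in-field calibration phantom into
    an uncalibrated HU volume under the scanner's forward model.

    The femur interior is filled at ``trabecular_density`` with a cortical
    shell at ``cortical_density``; background is 0 mg/cc equivalent density
    (soft tissue / water).  Phantom rods run along y below the femur.
    Deterministic given the seed.
    """
    geom = params.geometry
    if geom.neck_radius < 1.5 * voxel_mm:
        raise DegenerateGeometryError(
            f"voxel_mm={voxel_mm} too coarse: neck radius {geom.neck_radius} "
            "must span >= 3 voxels"
        )
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if rod_radius is None:
        # keep the rod cross-section resolved at coarse voxel sizes
        rod_radius = max(6.0, 2.2 * voxel_mm)

    tilt = np.deg2rad(180.0 - geom.neck_shaft_angle)
    head_cx = (geom.neck_length * np.sin(tilt)
               + geom.head_radius)  # medial extent
    pad = 2.0 * voxel_mm
    # Phantom rods sit below the femur (z < 0).
    rod_z = -(rod_radius + pad)
    x_lo = -(geom.shaft_radius + pad + rod_radius)
    x_hi = head_cx + pad
    y_lo = -(geom.neck_radius + pad + rod_radius)
    y_hi = geom.neck_radius + pad + rod_radius
    z_lo = rod_z - rod_radius - pad
    z_hi = (geom.shaft_length - geom.shaft_radius
            + geom.neck_length * np.cos(tilt) + geom.head_radius + pad)

    nx = int(np.ceil((x_hi - x_lo) / voxel_mm))
    ny = int(np.ceil((y_hi - y_lo) / voxel_mm))
    nz = int(np.ceil((z_hi - z_lo) / voxel_mm))
    # voxel-centre coordinates
    cx = x_lo + (np.arange(nx) + 0.5) * voxel_mm
    cy = y_lo + (np.arange(ny) + 0.5) * voxel_mm
    cz = z_lo + (np.arange(nz) + 0.5) * voxel_mm
    xx, yy, zz = np.meshgrid(cx, cy, cz, indexing="ij")

    mask, head_center = _femur_mask(geom, xx, yy, zz)
    n_erode = max(1, int(round(geom.cortical_thickness / voxel_mm)))
    interior = ndimage.binary_erosion(mask, iterations=n_erode)
    shell = mask & ~interior

    density = np.zeros((nx, ny, nz))  # mg/cc equivalent
    density[interior] = params.trabecular_density * 1000.0
    density[shell] = params.cortical_density * 1000.0

    # Phantom rods: cylinders along y, spread in x at fixed z.
    rod_xs = np.linspace(x_lo + rod_radius + pad,
                         x_hi - rod_radius - pad, len(rod_densities))
    phantom_rois: list[tuple[np.ndarray, float]] = []
    for rx, nominal in zip(rod_xs, rod_densities):
        rod = ((xx - rx) ** 2 + (zz - rod_z) ** 2) <= rod_radius ** 2
        density[rod] = nominal
        # ROI: inner core away from partial-volume edges, but never smaller
        # than one voxel half-diagonal so it always contains voxel centres
        roi_r = max(0.5 * rod_radius, 0.75 * voxel_mm)
        roi = ((xx - rx) ** 2 + (zz - rod_z) ** 2) <= roi_r ** 2
        phantom_rois.append((roi, float(nominal)))

    hu = scanner.hu_slope * density + scanner.hu_intercept
    if scanner.noise_sd > 0:
        hu = hu + rng.normal(0.0, scanner.noise_sd, hu.shape)

    meta = {
        "subject_id": params.subject_id,
        "origin_mm": (float(x_lo), float(y_lo), float(z_lo)),
        "head_center_mm": tuple(float(v) for v in head_center),
        "head_radius_mm": float(geom.head_radius),
        "femur_mask": mask,
        "interior_mask": interior,
    }
    return QCTVolume(grid=hu, spacing=(voxel_mm,) * 3, calibrated=False,
                     phantom_rois=phantom_rois,
                     scanner_id=scanner.scanner_id, meta=meta)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(cohort_spec: str | CohortSpec, n: int,
                    seed: int | np.random.Generator = 0,
                    scanner_id: str = "scanner-0") -> list[SubjectParams]:
    """Sample ``n`` subjects from truncated-normal demographic and density
    distributions.  ``cohort_spec`` names a built-in cohort or is a custom
    :class:`CohortSpec`.  Deterministic given the seed."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if isinstance(cohort_spec, str):
        try:
            spec = COHORT_SPECS[cohort_spec]
        except KeyError:
            raise ValueError(
                f"unknown cohort {cohort_spec!r}; choose from "
                f"{sorted(COHORT_SPECS)}") from None
    else:
        spec = cohort_spec
    if n == 0:
        return []
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    ages = _draw_truncnorm(rng, *spec.age, size=n)
    heights = _draw_truncnorm(rng, *spec.height, size=n)
    weights = _draw_truncnorm(rng, *spec.weight, size=n)
    shift = 1.0 + spec.density_shift
    cort = _draw_truncnorm(rng, spec.cortical_density[0] * shift,
                           spec.cortical_density[1],
                           (spec.cortical_density[2][0] * shift,
                            spec.cortical_density[2][1]), size=n)
    trab = _draw_truncnorm(rng, spec.trabecular_density[0] * shift,
                           spec.trabecular_density[1],
                           (max(0.02, spec.trabecular_density[2][0] * shift),
                            spec.trabecular_density[2][1]), size=n)
    if spec.sex == "mixed":
        sexes = np.where(rng.random(n) < 0.75, "male", "female")
    else:
        sexes = np.full(n, spec.sex, dtype=object)
    durations = (None if spec.flight_duration is None
                 else _draw_truncnorm(rng, *spec.flight_duration, size=n))

    base = FemurGeometry()
    subjects = []
    for i in range(n):
        # Scale the skeleton mildly with stature.
        s = float(np.clip(heights[i] / 175.0, 0.85, 1.15))
        geom = FemurGeometry(
            head_radius=base.head_radius * s,
            neck_radius=base.neck_radius * s,
            neck_length=base.neck_length * s,
            neck_shaft_angle=base.neck_shaft_angle,
            shaft_radius=base.shaft_radius * s,
            shaft_length=base.shaft_length * s,
            cortical_thickness=base.cortical_thickness,
        )
        subjects.append(SubjectParams(
            subject_id=f"{spec.name}-{i:04d}",
            age=float(ages[i]), sex=str(sexes[i]),
            height=float(heights[i]), weight=float(weights[i]),
            geometry=geom,
            cortical_density=float(cort[i]),
            trabecular_density=float(min(trab[i], 0.95 * cort[i])),
            scanner_id=scanner_id,
            flight_duration=(None if durations is None
                             else float(durations[i])),
        ))
    return subjects


# ---------------------------------------------------------------------------
# Spaceflight bone-loss effect
# ---------------------------------------------------------------------------

#: Default monthly loss rates, % per 30-day month.  Spaceflight QCT studies
#: report faster trabecular than cortical loss at the hip; the default keeps
#: that ordering at a 1.5:1 ratio, with magnitudes sized to the few-percent
#: total-hip losses seen on ~5-month missions flown with resistive-exercise
#: countermeasures.  Magnitudes are configurable.
DEFAULT_LOSS_MODEL = {"trabecular": 0.9, "cortical": 0.6}


def apply_flight_effect(params: SubjectParams,
                        loss_model: dict | None = None,
                        duration: float | None = None,
                        seed: int | np.random.Generator = 0,
                        noise_sd: float = 0.1,
                        allow_gain: bool = False) -> SubjectParams:
    """Return post-flight params with compartment densities reduced by a
    multiplicative exponential-decay model.

    ``loss_model`` gives percent lost per 30-day month for each compartment;
    the density after ``t`` months is ``rho * (1 - pct/100)**t`` times a
    subject-level lognormal noise factor (``noise_sd`` on the log-loss
    scale).  Duration 0 is the identity.  Negative rates (bone gain) must be
    explicitly enabled via ``allow_gain``.
    """
    lm = dict(DEFAULT_LOSS_MODEL if loss_model is None else loss_model)
    if duration is None:
        duration = params.flight_duration or 0.0
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if not allow_gain and any(v < 0 for v in lm.values()):
        raise ValueError("negative loss rates require allow_gain=True")
    if duration == 0:
        return params
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    months = duration / 30.0
    noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0

    def _decay(rho: float, pct_per_month: float) -> float:
        log_rate = -np.log1p(-pct_per_month / 100.0)  # per month, >0 for loss
        return float(rho * np.exp(-(log_rate * (1.0 + noise)) * months))

    return replace(
        params,
        trabecular_density=_decay(params.trabecular_density, lm["trabecular"]),
        cortical_density=_decay(params.cortical_density, lm["cortical"]),
    )


# ---------------------------------------------------------------------------
# Projected DXA
# ---------------------------------------------------------------------------

def project_dxa(volume: QCTVolume, axis: int = 1,
                ref_mean: float = DEFAULT_TSCORE_REF[0],
                ref_sd: float = DEFAULT_TSCORE_REF[1],
                mask: np.ndarray | None = None,
                scan_day: float = 0.0) -> DXAMeasure:
    """Project the calibrated volume's femur mask along ``axis`` into an
    areal BMD, ``aBMD = (sum density * voxel volume) / projected area`` in
    g/cm^2, and compute the T-score against the (ref_mean, ref_sd) young-
    adult reference."""
    if not volume.calibrated:
        raise ValueError("project_dxa requires a calibrated volume")
    if mask is None:
        mask = volume.meta.get("femur_mask")
    if mask is None or not np.any(mask):
        raise ValueError("empty or missing femur mask")
    dens_g_cm3 = volume.grid / 1000.0  # mg/cc -> g/cm^3
    vox_cm3 = volume.voxel_volume_mm3 / 1000.0
    bmc_g = float(np.sum(dens_g_cm3[mask]) * vox_cm3)
    proj = np.any(mask, axis=axis)
    sp = [s for i, s in enumerate(volume.spacing) if i != axis]
    area_cm2 = float(np.count_nonzero(proj) * sp[0] * sp[1] / 100.0)
    abmd = bmc_g / area_cm2
    t = (abmd - ref_mean) / ref_sd
    return DXAMeasure(aBMD=abmd, t_score=t, scan_day=scan_day)
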