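"""HU-to-density calibration and scanner cross-calibration.

Every QCT scan carries an in-field phantom with rods of known mineral-
equivalent density.  Calibration regresses the nominal rod densities on the
observed ROI-mean HU (ordinary least squares; the nominals are exact, so the
regression runs nominal-on-HU rather than inverse prediction) and applies
the fitted affine map voxelwise.  Cross-calibration relates calibrated
densities of the same physical regions seen on two scanners, again as an
affine map applied at the voxel level, so that all capacity estimates live
on a single reference density scale.  DXA areal BMD from different
manufacturers is harmonised with configured linear equations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .synth_cohort import QCTVolume

__all__ = [
    "CalibrationFit",
    "CrossCalibration",
    "DXACrossCal",
    "InsufficientPhantomError",
    "fit_phantom_calibration",
    "apply_calibration",
    "fit_cross_calibration",
    "apply_cross_calibration",
    "dxa_cross_calibrate",
]


class InsufficientPhantomError(ValueError):
    """Fewer than two distinct phantom rod densities available."""


@dataclass(frozen=True)
class CalibrationFit:
    """Affine HU -> mg/cc map: density = slope * HU + intercept."""

    slope: float
    intercept: float
    r_squared: float
    rod_table: tuple[tuple[float, float], ...]  # (nominal mg/cc, mean HU)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class CrossCalibration:
    """Affine map taking source-scanner densities onto the target scanner's
    density scale: rho_target = slope * rho_source + intercept."""

    source_scanner_id: str
    target_scanner_id: str
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("cross-calibration slope must be > 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class DXACrossCal:
    """Linear aBMD harmonisation between DXA manufacturers,
    aBMD_target = slope * aBMD_source + intercept (g/cm^2).  Coefficients are
    configuration: the published conversion equations are instrument-specific
    and supplied by the user."""

    source_model: str
    target_model: str
    slope: float = 1.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("DXA cross-calibration slope must be > 0")


def fit_phantom_calibration(volume: QCTVolume) -> CalibrationFit:
    """OLS of nominal rod density (mg/cc) on observed ROI-mean HU."""
    rois = volume.phantom_rois
    nominals = [d for _, d in rois]
    if len(set(nominals)) < 2:
        raise InsufficientPhantomError(
            "need >= 2 phantom rods with distinct nominal densities")
    hu_means = np.array([float(volume.grid[m].mean()) for m, _ in rois])
    noms = np.array(nominals, dtype=float)
    if np.ptp(hu_means) == 0:
        raise ValueError("degenerate fit: zero HU variance across rods")
    res = stats.linregress(hu_means, noms)
    return CalibrationFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        rod_table=tuple((float(n), float(h)) for n, h in zip(noms, hu_means)),
    )


def apply_calibration(volume: QCTVolume, fit: CalibrationFit) -> QCTVolume:
    """Map every voxel HU -> mg/cc through the fitted affine map and set the
    calibrated flag.  Refuses already-calibrated input."""
    if volume.calibrated:
        raise ValueError("volume is already calibrated")
    out = volume.copy()
    out.grid = fit.slope * volume.grid + fit.intercept
    out.calibrated = True
    out.meta = dict(out.meta, calibration={"slope": fit.slope,
                                           "intercept": fit.intercept})
    return out


def _region_means(volume: QCTVolume) -> dict[str, float]:
    """Mean calibrated density per named region: phantom rods plus, when the
    generator metadata is present, the femur cortical shell and trabecular
    interior of the scanned subject."""
    regions: dict[str, float] = {}
    for i, (mask, nominal) in enumerate(volume.phantom_rois):
        regions[f"rod{i}_{nominal:g}"] = float(volume.grid[mask].mean())
    femur = volume.meta.get("femur_mask")
    interior = volume.meta.get("interior_mask")
    if femur is not None and interior is not None:
        shell = femur & ~interior
        if shell.any():
            regions["cortical_shell"] = float(volume.grid[shell].mean())
        if interior.any():
            regions["trabecular_interior"] = float(volume.grid[interior].mean())
    return regions


def fit_cross_calibration(phantom_on_target: QCTVolume,
                          phantom_on_source: QCTVolume) -> CrossCalibration:
    """Regress target-scanner region-mean densities on source-scanner ones
    for the same physical regions, yielding the affine map that carries
    source densities onto the target scanner's scale.

    Region means (not raw voxels) are used to suppress noise; regions are the
    phantom rods plus the femur compartments of the scanned subject when
    available.
    """
    if not (phantom_on_target.calibrated and phantom_on_source.calibrated):
        raise ValueError("both volumes must be calibrated on their scanners")
    ra = _region_means(phantom_on_target)
    rb = _region_means(phantom_on_source)
    common = sorted(set(ra) & set(rb))
    if len(common) < 2:
        raise ValueError("need >= 2 shared regions for cross-calibration")
    a = np.array([ra[k] for k in common])
    b = np.array([rb[k] for k in common])
    if np.ptp(b) == 0:
        raise ValueError("degenerate cross-calibration: no density spread")
    res = stats.linregress(b, a)
    return CrossCalibration(
        source_scanner_id=phantom_on_source.scanner_id,
        target_scanner_id=phantom_on_target.scanner_id,
        slope=float(res.slope), intercept=float(res.intercept),
    )


def apply_cross_calibration(volume: QCTVolume,
                            xcal: CrossCalibration) -> QCTVolume:
    """Apply the cross-calibration map voxelwise and rewrite scanner_id."""
    if volume.scanner_id != xcal.source_scanner_id:
        raise ValueError(
            f"volume scanner {volume.scanner_id!r} does not match "
            f"cross-calibration source {xcal.source_scanner_id!r}")
    if not volume.calibrated:
        raise ValueError("cross-calibration applies to calibrated volumes")
    out = volume.copy()
    out.grid = xcal.slope * volume.grid + xcal.intercept
    out.scanner_id = xcal.target_scanner_id
    out.meta = dict(out.meta, cross_calibration={
        "from": xcal.source_scanner_id, "to": xcal.target_scanner_id,
        "slope": xcal.slope, "intercept": xcal.intercept})
    return out


def dxa_cross_calibrate(abmd: float, cal: DXACrossCal) -> float:
    """Harmonise an areal BMD value between DXA manufacturers."""
    if abmd < 0:
        raise ValueError("aBMD must be >= 0")
    return cal.slope * abmd + cal.intercept
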