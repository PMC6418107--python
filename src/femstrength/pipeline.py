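"""End-to-end orchestration: simulate -> calibrate -> FE -> cut-points ->
PRA -> report, with NIfTI/CSV/JSON I/O and a reproducibility manifest.

A single master seed in the config drives every stage through a documented
counter scheme (stage seed = (master * 100003 + stage index) mod 2^31;
subject-level generators add the subject index), so rerunning a config
reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import nibabel as nib

from . import __version__
from .synth_cohort import (
    QCTVolume, ScannerModel, SubjectParams, apply_flight_effect,
    generate_cohort, generate_volume, project_dxa,
)
from .density_cal import apply_calibration, fit_phantom_calibration
from .voxel_fe import FEResult, MaterialCurve, SolveConfig, run_configuration
from .risk_bands import (
    RiskBandConfig, SubjectRecord, classify_postflight, classify_preflight,
    derive_pol, summarize_cohort,
)
from .pra_overload import mission_report

__all__ = ["RunManifest", "DEFAULT_CONFIG", "load_config", "run_pipeline",
           "read_volume", "write_volume", "stage_seed"]

STAGES = ("simulate", "calibrate", "fe", "cutpoints", "pra", "report")

#: Demo-scale defaults: 8 astronaut-like subjects with paired pre/post
#: scans, a small fractured reference cohort for POL derivation, coarse
#: voxels so the whole chain runs in minutes on one CPU.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGES),
    "cohort": {"name": "astronaut", "n": 8, "voxel_mm": 6.0},
    "scanner": {"scanner_id": "scanner-0", "hu_slope": 0.8,
                "hu_intercept": 10.0, "noise_sd": 2.0},
    "flight": {"trabecular_pct_per_month": 0.9,
               "cortical_pct_per_month": 0.6, "noise_sd": 0.1},
    "reference_cohort": {"name": "AGES_fractured", "n": 12,
                         "voxel_mm": 6.0},
    "fe": {"bone_threshold": 100.0,
           "curve": {},               # MaterialCurve overrides
           "solve": {"displacement_increment": 0.4, "max_steps": 30}},
    "bands": {},                      # RiskBandConfig overrides
    "pra": {"n": 100000, "method": "closed_form"},
    "write_volumes": False,
}


class ConfigError(ValueError):
    pass


class DependencyError(RuntimeError):
    pass


@dataclass
class RunManifest:
    """Traceability record: config snapshot, per-stage seeds, software
    version, output-file digests, and timestamps."""

    config: dict
    seeds: dict[str, int] = field(default_factory=dict)
    version: str = ""
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stages_completed: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   sort_keys=True))


def stage_seed(master: int, stage: str) -> int:
    """Counter-scheme per-stage seed below 2^31."""
    return (int(master) * 100003 + STAGES.index(stage)) % (2 ** 31)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Merge a YAML config file over the documented defaults and validate
    keys; unknown top-level keys are a schema error."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    user = {}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        user = {**user, **overrides}
    bad = sorted(set(user) - set(DEFAULT_CONFIG))
    if bad:
        raise ConfigError(f"unknown config keys: {bad}")
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    unknown_stages = sorted(set(cfg["stages"]) - set(STAGES))
    if unknown_stages:
        raise ConfigError(f"unknown stages: {unknown_stages}")
    return cfg


# ---------------------------------------------------------------------------
# Volume I/O: NIfTI grid + label volume for masks + JSON sidecar
# ---------------------------------------------------------------------------

def write_volume(volume: QCTVolume, path: str | Path) -> None:
    """Write the grid as NIfTI with a same-grid label volume for the masks
    (1 shell, 2 interior, 10+i phantom rods) and a JSON sidecar for scalar
    metadata.  Round-trips losslessly through :func:`read_volume`."""
    path = Path(path)
    if path.suffix not in (".nii",) and not path.name.endswith(".nii.gz"):
        raise ValueError(f"unrecognised volume format: {path.name}")
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.grid.astype(np.float64), affine), path)

    labels = np.zeros(volume.grid.shape, dtype=np.uint8)
    femur = volume.meta.get("femur_mask")
    interior = volume.meta.get("interior_mask")
    if femur is not None:
        labels[femur] = 1
    if interior is not None:
        labels[interior] = 2
    for i, (mask, _) in enumerate(volume.phantom_rois):
        labels[mask] = 10 + i
    lbl_path = _sidecar(path, "_labels.nii.gz")
    nib.save(nib.Nifti1Image(labels, affine), lbl_path)

    meta = {k: v for k, v in volume.meta.items()
            if not isinstance(v, np.ndarray)}
    sidecar = {
        "scanner_id": volume.scanner_id,
        "calibrated": volume.calibrated,
        "spacing": list(volume.spacing),
        "rod_nominals": [d for _, d in volume.phantom_rois],
        "meta": meta,
    }
    _sidecar(path, ".json").write_text(json.dumps(sidecar, indent=2))


def _sidecar(path: Path, suffix: str) -> Path:
    stem = path.name[:-7] if path.name.endswith(".nii.gz") else path.stem
    return path.with_name(stem + suffix)


def read_volume(path: str | Path) -> QCTVolume:
    """Read a volume written by :func:`write_volume` (grid, spacing, masks,
    scalar metadata)."""
    path = Path(path)
    if path.suffix not in (".nii",) and not path.name.endswith(".nii.gz"):
        raise ValueError(f"unrecognised volume format: {path.name}")
    img = nib.load(str(path))
    grid = np.asarray(img.dataobj, dtype=np.float64)
    side_path = _sidecar(path, ".json")
    if not side_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {side_path}")
    side = json.loads(side_path.read_text())
    spacing = tuple(side["spacing"])
    if any(s <= 0 for s in spacing):
        raise ValueError("non-positive spacing in sidecar")
    meta = dict(side.get("meta", {}))
    lbl_path = _sidecar(path, "_labels.nii.gz")
    rois = []
    if lbl_path.exists():
        labels = np.asarray(nib.load(str(lbl_path)).dataobj)
        femur = (labels == 1) | (labels == 2)
        if femur.any():
            meta["femur_mask"] = femur
            meta["interior_mask"] = labels == 2
        for i, nominal in enumerate(side.get("rod_nominals", [])):
            rois.append((labels == 10 + i, float(nominal)))
    return QCTVolume(grid=grid, spacing=spacing,
                     calibrated=bool(side["calibrated"]),
                     phantom_rois=rois, scanner_id=side["scanner_id"],
                     meta=meta)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _simulate_and_fe(subjects: list[SubjectParams], scanner: ScannerModel,
                     voxel_mm: float, curve: MaterialCurve,
                     solve_cfg: SolveConfig, bone_threshold: float,
                     seed: int, with_flight: bool, flight_cfg: dict,
                     outdir: Path | None) -> list[SubjectRecord]:
    """Generate, calibrate, optionally fly, and FE-analyse each subject."""
    records = []
    for i, params in enumerate(subjects):
        rec = SubjectRecord(params=params, cohort_label=params.subject_id
                            .rsplit("-", 1)[0])
        timepoints = [("pre", params)]
        if with_flight:
            post = apply_flight_effect(
                params,
                loss_model={"trabecular": flight_cfg["trabecular_pct_per_month"],
                            "cortical": flight_cfg["cortical_pct_per_month"]},
                seed=seed + 7919 * (i + 1),
                noise_sd=flight_cfg.get("noise_sd", 0.1))
            timepoints.append(("post", post))
        for when, p in timepoints:
            vol = generate_volume(p, scanner, voxel_mm=voxel_mm,
                                  seed=seed + 2 * i + (when == "post"))
            fit = fit_phantom_calibration(vol)
            cal = apply_calibration(vol, fit)
            if outdir is not None:
                write_volume(cal, outdir / f"{p.subject_id}_{when}.nii.gz")
            dxa = project_dxa(cal, scan_day=(-90.0 if when == "pre" else 8.0))
            nls = run_configuration(cal, "NLS", curve, solve_cfg,
                                    bone_threshold)
            nlf = run_configuration(cal, "NLF", curve, solve_cfg,
                                    bone_threshold)
            if when == "pre":
                rec.dxa_pre, rec.f_nls_pre, rec.f_nlf_pre = (
                    dxa, nls.load_capacity, nlf.load_capacity)
            else:
                rec.dxa_post, rec.f_nls_post, rec.f_nlf_post = (
                    dxa, nls.load_capacity, nlf.load_capacity)
        records.append(rec)
    return records


def _records_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        p = r.params
        rows.append({
            "subject_id": p.subject_id, "cohort": r.cohort_label,
            "age": p.age, "sex": p.sex, "height": p.height,
            "weight": p.weight,
            "flight_duration": p.flight_duration,
            "abmd_pre": r.dxa_pre.aBMD if r.dxa_pre else None,
            "t_score_pre": r.dxa_pre.t_score if r.dxa_pre else None,
            "abmd_post": r.dxa_post.aBMD if r.dxa_post else None,
            "t_score_post": r.dxa_post.t_score if r.dxa_post else None,
            "f_nls_pre": r.f_nls_pre, "f_nls_post": r.f_nls_post,
            "f_nlf_pre": r.f_nlf_pre, "f_nlf_post": r.f_nlf_post,
        })
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def run_pipeline(config: dict | str | Path | None = None,
                 outdir: str | Path = "femstrength_out") -> RunManifest:
    """Execute the enabled stages in order and write all outputs plus the
    manifest under ``outdir``.  Rerunning with the same config and seed
    reproduces identical CSV/JSON outputs."""
    cfg = (config if isinstance(config, dict)
           else load_config(config))
    stages = list(cfg["stages"])
    if ("cutpoints" in stages or "report" in stages) and "fe" not in stages:
        raise DependencyError(
            "classification/report stages require the 'fe' stage")
    if "fe" in stages and "calibrate" not in stages:
        raise DependencyError("'fe' requires the 'calibrate' stage")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    manifest = RunManifest(config=cfg, version=__version__,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    for st in STAGES:
        manifest.seeds[st] = stage_seed(master, st)

    scanner = ScannerModel(**cfg["scanner"])
    curve = MaterialCurve(**cfg["fe"]["curve"])
    solve_cfg = SolveConfig(**cfg["fe"]["solve"])
    bands = RiskBandConfig(**cfg["bands"])
    bone_thr = cfg["fe"]["bone_threshold"]
    vol_dir = outdir / "volumes" if cfg.get("write_volumes") else None
    if vol_dir is not None:
        vol_dir.mkdir(exist_ok=True)

    try:
        records: list[SubjectRecord] = []
        ref_caps_nls: list[float] = []
        ref_caps_nlf: list[float] = []
        if {"simulate", "calibrate", "fe"} <= set(stages):
            subjects = generate_cohort(
                cfg["cohort"]["name"], cfg["cohort"]["n"],
                seed=manifest.seeds["simulate"],
                scanner_id=scanner.scanner_id)
            records = _simulate_and_fe(
                subjects, scanner, cfg["cohort"]["voxel_mm"], curve,
                solve_cfg, bone_thr, seed=manifest.seeds["fe"],
                with_flight=True, flight_cfg=cfg["flight"], outdir=vol_dir)
            df = _records_frame(records)
            _write_csv(df, outdir / "subjects.csv")
            manifest.stages_completed += ["simulate", "calibrate", "fe"]

            # reference cohort for POL derivation (single pre scan each)
            ref = generate_cohort(
                cfg["reference_cohort"]["name"], cfg["reference_cohort"]["n"],
                seed=manifest.seeds["simulate"] + 1,
                scanner_id=scanner.scanner_id)
            ref_records = _simulate_and_fe(
                ref, scanner, cfg["reference_cohort"]["voxel_mm"], curve,
                solve_cfg, bone_thr, seed=manifest.seeds["fe"] + 1,
                with_flight=False, flight_cfg=cfg["flight"], outdir=None)
            ref_caps_nls = [r.f_nls_pre for r in ref_records]
            ref_caps_nlf = [r.f_nlf_pre for r in ref_records]
            _write_csv(_records_frame(ref_records),
                       outdir / "reference_cohort.csv")

        if "cutpoints" in stages:
            pol_nls = derive_pol(ref_caps_nls, bands.percentile_q)
            pol_nlf = derive_pol(ref_caps_nlf, bands.percentile_q)
            derived = dataclasses.replace(bands, pol_nls=pol_nls,
                                          pol_nlf=pol_nlf)
            (outdir / "cutpoints.json").write_text(json.dumps({
                "percentile_q": bands.percentile_q,
                "derived_pol_nls_N": pol_nls,
                "derived_pol_nlf_N": pol_nlf,
                "adopted_pol_nls_N": bands.pol_nls,
                "adopted_pol_nlf_N": bands.pol_nlf,
                "percentile_method": "linear interpolation between closest ranks",
                "n_reference": len(ref_caps_nls),
            }, indent=2))
            cls_rows = []
            for r in records:
                pre = classify_preflight(r.dxa_pre.t_score, r.f_nls_pre,
                                         bands)
                post = classify_postflight(r.dxa_post.t_score, r.f_nls_post,
                                           r.f_nlf_post, r, bands)
                cls_rows.append({
                    "subject_id": r.params.subject_id,
                    "preflight_decision": pre.preflight_decision,
                    "preflight_quadrant": pre.quadrant,
                    "postflight_quadrant": post.quadrant,
                    "postflight_flags": ";".join(sorted(post.postflight_flags)),
                    "nls_change_pct": post.changes.get("nls_change_pct"),
                    "nlf_change_pct": post.changes.get("nlf_change_pct"),
                })
            _write_csv(pd.DataFrame(cls_rows), outdir / "classification.csv")
            manifest.stages_completed.append("cutpoints")

        if "pra" in stages:
            pra_df = mission_report(
                capacity_nlf=bands.pol_nlf, n=cfg["pra"]["n"],
                seed=manifest.seeds["pra"], method=cfg["pra"]["method"])
            _write_csv(pra_df, outdir / "pra.csv")
            manifest.stages_completed.append("pra")

        if "report" in stages and records:
            summary = summarize_cohort(records)
            summary.to_csv(outdir / "summary.csv", float_format="%.6g",
                           lineterminator="\n")
            manifest.stages_completed.append("report")
    finally:
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        for f in sorted(outdir.rglob("*")):
            if f.is_file() and f.name != "manifest.json":
                manifest.outputs[str(f.relative_to(outdir))] = (
                    hashlib.sha256(f.read_bytes()).hexdigest())
        manifest.write(outdir / "manifest.json")
    return manifest
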