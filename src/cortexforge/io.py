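"""File formats, configuration and the end-to-end pillar-ring pipeline.

Conventions: CSV with explicit unit-suffixed headers for tabular data, JSON
for structured results, multi-page grayscale TIFF plus a JSON sidecar
(``<path>.json`` holding the voxel size) for image stacks, and YAML or JSON
interchangeably for configuration.  All outputs are deterministic for a
fixed configuration and seed — reports carry no timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .beam import DeflectionProfile, PillarGeometry, fit_force, pillar_stiffness
from .errors import ValidationError
from .fitting import FitSpec, fit_model_to_trajectory
from .imaging import (Centerline, VoxelStack, extract_centerlines,
                      profiles_from_centerlines, segment_stack)
from .model import ModelParameters, ParameterSchedule, Trajectory
from .quantify import CalibrationSeries
from .synthetic import RenderSpec, TrajectoryNoiseSpec, gen_trajectory, \
    render_pillar_ring

logger = logging.getLogger("cortexforge")

__all__ = [
    "read_stack", "write_stack", "read_trajectory", "write_trajectory",
    "read_profile", "write_profiles", "write_centerlines",
    "read_calibration_series", "load_config", "parse_model_parameters",
    "parse_schedule", "parse_geometry", "PipelineConfig", "run_pipeline",
]


# ---------------------------------------------------------------- stacks

def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_stack(path, stack: VoxelStack) -> None:
    """Write a stack as multi-page TIFF plus a voxel-size JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.intensities, photometric="minisblack")
    _sidecar(path).write_text(json.dumps(
        {"voxel_size_um": list(stack.voxel_size)}, indent=0) + "\n")


def read_stack(path, voxel_size: Optional[tuple] = None) -> VoxelStack:
    """Read a multi-page grayscale TIFF as a :class:`VoxelStack`.

    The voxel size comes from the JSON sidecar written by
    :func:`write_stack`, or from the ``voxel_size`` argument; an error is
    raised if neither is available.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # malformed file
        raise ValidationError(f"cannot read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValidationError(
            f"{path}: expected a grayscale multi-page TIFF, got shape "
            f"{data.shape}")
    if voxel_size is None:
        sc = _sidecar(path)
        if not sc.exists():
            raise ValidationError(
                f"no voxel size: provide voxel_size or a sidecar {sc}")
        voxel_size = tuple(json.loads(sc.read_text())["voxel_size_um"])
    return VoxelStack(intensities=data, voxel_size=tuple(voxel_size))


# ------------------------------------------------------------- tabular IO

def write_trajectory(path, traj: Trajectory) -> None:
    traj.to_frame().to_csv(path, index=False)


def read_trajectory(path, n_pillars: int = 1) -> Trajectory:
    df = pd.read_csv(path)
    required = {"t_s", "x_um"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: trajectory CSV needs columns {required}")
    t = df["t_s"].to_numpy(float)
    x = df["x_um"].to_numpy(float)
    v = (df["v_um_per_s"].to_numpy(float) if "v_um_per_s" in df
         else np.gradient(x, t))
    get = lambda col: (df[col].to_numpy(float) if col in df
                       else np.zeros_like(t))
    return Trajectory(t=t, x=x, v=v, n_b=get("n_b"), F_A=get("F_A_pN"),
                      F_pillar=get("F_pillar_pN"), n_pillars=n_pillars)


def write_profiles(path, profiles: list[tuple[int, DeflectionProfile]]) -> None:
    rows = [(pid, z, w) for pid, prof in profiles
            for z, w in zip(prof.z, prof.w)]
    pd.DataFrame(rows, columns=["pillar_id", "z_um", "w_um"]).to_csv(
        path, index=False)


def read_profile(path) -> DeflectionProfile:
    df = pd.read_csv(path)
    if not {"z_um", "w_um"}.issubset(df.columns):
        raise ValidationError(f"{path}: profile CSV needs z_um,w_um columns")
    sigma = df["sigma_um"].to_numpy(float) if "sigma_um" in df else None
    return DeflectionProfile(z=df["z_um"].to_numpy(float),
                             w=df["w_um"].to_numpy(float), sigma=sigma)


def write_centerlines(path, centerlines: list[Centerline]) -> None:
    rows = [(c.pillar_id, z, cx, cy) for c in centerlines
            for z, cx, cy in zip(c.z, c.cx, c.cy)]
    pd.DataFrame(rows, columns=["pillar_id", "z_um", "cx_um", "cy_um"]).to_csv(
        path, index=False)


def read_calibration_series(path) -> CalibrationSeries:
    df = pd.read_csv(path)
    if not {"conc_uM", "mean_intensity"}.issubset(df.columns):
        raise ValidationError(
            f"{path}: calibration CSV needs conc_uM,mean_intensity columns")
    n_fields = (df["n_fields"].to_numpy(int) if "n_fields" in df else None)
    return CalibrationSeries(concentration=df["conc_uM"].to_numpy(float),
                             mean_intensity=df["mean_intensity"].to_numpy(float),
                             n_fields=n_fields)


# ------------------------------------------------------------ configuration

def load_config(path) -> dict:
    """Load a YAML or JSON configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return data


def _check_keys(block: dict, allowed: set, context: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValidationError(f"{context}: unknown key(s) {sorted(unknown)}")


def parse_model_parameters(block: dict) -> ModelParameters:
    allowed = {f.name for f in dataclasses.fields(ModelParameters)}
    _check_keys(block, allowed, "model")
    if "k_p" not in block:
        raise ValidationError("model: k_p is required")
    return ModelParameters(**block)


def parse_schedule(block: dict) -> ParameterSchedule:
    _check_keys(block, {"switches", "initial_binding"}, "schedule")
    switches = tuple((float(t), dict(over))
                     for t, over in block.get("switches", []))
    return ParameterSchedule(switches=switches,
                             initial_binding=block.get("initial_binding",
                                                       "unloaded"))


def parse_geometry(block: dict) -> PillarGeometry:
    allowed = {f.name for f in dataclasses.fields(PillarGeometry)}
    _check_keys(block, allowed, "geometry")
    return PillarGeometry(**block)


def parse_render_spec(block: dict, seed: int) -> RenderSpec:
    allowed = {f.name for f in dataclasses.fields(RenderSpec)} | {"geometry"}
    _check_keys(block, allowed, "render")
    block = dict(block)
    geom = parse_geometry(block.pop("geometry", {"L": 15.0, "d": 2.0,
                                                 "E_kPa": 57.0}))
    block.pop("seed", None)
    for key in ("voxel_size", "psf_sigma"):
        if key in block:
            block[key] = tuple(block[key])
    return RenderSpec(seed=seed, geometry=geom, **block)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of the end-to-end pipeline.

    Every stochastic stage receives an explicit seed derived from the global
    seed by a fixed offset (render: +1, trajectory noise: +2).
    """

    seed: int
    out_dir: str
    render: dict
    extraction: dict = dataclasses.field(default_factory=dict)
    modelfit: Optional[dict] = None
    log_level: str = "info"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        _check_keys(raw, {"seed", "out_dir", "render", "extraction",
                          "modelfit", "log_level"}, "pipeline")
        for key in ("seed", "out_dir", "render"):
            if key not in raw:
                raise ValidationError(f"pipeline: {key} is required")
        _check_keys(raw.get("extraction", {}),
                    {"threshold_method", "min_area_voxels",
                     "min_seed_separation_um", "max_link_um",
                     "expected_pillars"}, "extraction")
        if raw.get("modelfit") is not None:
            _check_keys(raw["modelfit"],
                        {"model", "noise_sigma", "duration", "interval",
                         "free", "n_starts"}, "modelfit")
        cfg = cls(seed=int(raw["seed"]), out_dir=str(raw["out_dir"]),
                  render=dict(raw["render"]),
                  extraction=dict(raw.get("extraction", {})),
                  modelfit=raw.get("modelfit"),
                  log_level=str(raw.get("log_level", "info")))
        # validate eagerly so mismatches fail before any stage runs
        spec = parse_render_spec(cfg.render, seed=cfg.seed + 1)
        expected = cfg.extraction.get("expected_pillars")
        if expected is not None and int(expected) != spec.n_pillars:
            raise ValidationError(
                f"extraction expects {expected} pillars but render produces "
                f"{spec.n_pillars}")
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Render → extract → beam-fit (→ optionally model-fit), with provenance.

    Writes all intermediate files under ``config.out_dir`` and returns the
    report dict (also written as ``report.json``).  Idempotent: identical
    configuration and seed give byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config),
                    "seeds": {"global": config.seed, "render": config.seed + 1,
                              "trajectory_noise": config.seed + 2},
                    "stages": {}, "outputs": {}}
    stage = "render"
    try:
        spec = parse_render_spec(config.render, seed=config.seed + 1)
        logger.info("[render] %d pillars, ring D = %g µm",
                    spec.n_pillars, spec.ring_diameter)
        before, after, truth = render_pillar_ring(spec)
        write_stack(out / "before.tif", before)
        write_stack(out / "after.tif", after)
        report["outputs"]["before_tif"] = str(out / "before.tif")
        report["outputs"]["after_tif"] = str(out / "after.tif")
        report["stages"]["render"] = {
            "true_forces_pN": truth.forces.tolist(),
            "tip_deflections_um": truth.tip_deflections.tolist()}

        stage = "extract"
        ext = {k: v for k, v in config.extraction.items()
               if k != "expected_pillars"}
        logger.info("[extract] segmenting before/after stacks")
        cl_before = extract_centerlines(segment_stack(before, **ext), before)
        cl_after = extract_centerlines(segment_stack(after, **ext), after)
        write_centerlines(out / "centerlines_before.csv", cl_before)
        write_centerlines(out / "centerlines_after.csv", cl_after)
        profiles = profiles_from_centerlines(cl_before, cl_after,
                                             truth.ring_centre)
        write_profiles(out / "profiles.csv", profiles)
        report["outputs"]["profiles_csv"] = str(out / "profiles.csv")
        report["stages"]["extract"] = {
            "n_pillars_before": len(cl_before),
            "n_pillars_after": len(cl_after)}

        stage = "beamfit"
        logger.info("[beamfit] fitting %d profiles", len(profiles))
        geom = spec.geometry
        fits = {}
        for pid, prof in profiles:
            F_hat, rms = fit_force(prof, geom=geom)
            fits[str(pid)] = {"F_pN": F_hat, "residual_rms_um": rms}
        report["stages"]["beamfit"] = {
            "k_p_pN_per_um": pillar_stiffness(geom), "forces": fits}

        if config.modelfit is not None:
            stage = "modelfit"
            mf = config.modelfit
            params = parse_model_parameters(mf["model"])
            noise = TrajectoryNoiseSpec(
                sigma=float(mf.get("noise_sigma", 0.05)),
                interval=float(mf.get("interval", 1.0)),
                duration=float(mf.get("duration", 600.0)),
                seed=config.seed + 2)
            logger.info("[modelfit] generating and fitting trajectory")
            observed, _ = gen_trajectory(params, noise)
            write_trajectory(out / "trajectory.csv", observed)
            fspec = FitSpec(free=tuple(mf.get("free",
                                              ("gamma_am", "f_d", "n_m_f_s",
                                               "k_off0"))),
                            n_starts=int(mf.get("n_starts", 5)),
                            seed=config.seed)
            fit = fit_model_to_trajectory(observed, fspec, k_p=params.k_p,
                                          base_params=params)
            report["stages"]["modelfit"] = {
                "free_values": fit.free_values, "loss": fit.loss,
                "converged": fit.converged, "at_bounds": fit.at_bounds}
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True) + "\n")
        raise
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                sort_keys=True) + "\n")
    return report
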