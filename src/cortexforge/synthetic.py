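"""Seeded synthetic-data generators with ground truth for every output.

Three generators emulate the pillar-ring assay inputs end to end:

* :func:`gen_trajectory` — contraction time series from the contractility
  model plus i.i.d. Gaussian measurement noise on the tip position, with the
  noiseless truth returned alongside.
* :func:`render_pillar_ring` — before/after 3D fluorescence stacks of a
  pillar ring.  Pillars are circular cylinders on a ring, bent according to
  Euler-beam theory under the specified per-pillar forces, blurred with an
  anisotropic Gaussian PSF and corrupted with Poisson and/or Gaussian read
  noise.  The renderer's centrelines and forces are returned as ground
  truth so the image pipeline and beam fit can be validated in closed loop.
* :func:`gen_calibration_series` — a linear fluorescence dilution series
  with additive Gaussian noise.

Every stochastic output requires an explicit seed and is bit-reproducible
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .beam import PillarGeometry, _unit_profile
from .errors import ValidationError
from .imaging import Centerline, VoxelStack
from .model import ModelParameters, ParameterSchedule, Trajectory, \
    simulate_contraction
from .quantify import CalibrationSeries

__all__ = [
    "TrajectoryNoiseSpec",
    "RenderSpec",
    "RenderTruth",
    "gen_trajectory",
    "render_pillar_ring",
    "gen_calibration_series",
]


@dataclass(frozen=True)
class TrajectoryNoiseSpec:
    """Measurement noise and sampling for synthetic contraction curves."""

    sigma: float = 0.05
    interval: float = 1.0
    duration: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError(f"sigma must be >= 0, got {self.sigma}")
        if self.interval <= 0 or self.duration <= 0:
            raise ValidationError("interval and duration must be > 0")


def gen_trajectory(params: ModelParameters,
                   noise: TrajectoryNoiseSpec,
                   schedule: ParameterSchedule | None = None
                   ) -> tuple[Trajectory, Trajectory]:
    """Simulate a contraction and add Gaussian measurement noise to ``x``.

    The observed velocity is recomputed from the noisy positions by central
    differences (as it would be from tracked experimental positions), and
    the observed pillar force is ``k_p`` times the noisy position.  The
    bound-motor and active-force series are not observable and are carried
    over from the truth.

    Returns ``(observed, truth)``.
    """
    truth = simulate_contraction(params, schedule=schedule,
                                 t_end=noise.duration, dt_out=noise.interval)
    rng = np.random.default_rng(noise.seed)
    x_obs = truth.x + rng.normal(0.0, noise.sigma, size=len(truth))
    v_obs = np.gradient(x_obs, truth.t)
    observed = Trajectory(t=truth.t, x=x_obs, v=v_obs, n_b=truth.n_b,
                          F_A=truth.F_A, F_pillar=params.k_p * x_obs,
                          n_pillars=truth.n_pillars)
    return observed, truth


@dataclass(frozen=True)
class RenderSpec:
    """Geometry, optics and noise for rendering a pillar-ring z-stack.

    ``forces`` is either a scalar applied to every pillar or one value per
    pillar (pN, directed toward the ring centre).  The lateral voxel size
    default matches a confocal pixel scaling of 0.099 × 0.099 µm²; the
    axial step and PSF widths are nominal confocal values.
    """

    seed: int
    n_pillars: int = 10
    ring_diameter: float = 26.0
    geometry: PillarGeometry = field(
        default_factory=lambda: PillarGeometry(L=15.0, d=2.0, E_kPa=57.0))
    forces: float | Sequence[float] = 126.0
    voxel_size: tuple[float, float, float] = (0.5, 0.099, 0.099)
    psf_sigma: tuple[float, float, float] = (0.3, 0.15, 0.15)
    background: float = 20.0
    amplitude: float = 200.0
    noise_model: str = "mixed"
    read_sigma: float = 5.0
    margin: float = 3.0

    def __post_init__(self) -> None:
        if self.n_pillars < 1:
            raise ValidationError("n_pillars must be >= 1")
        if self.ring_diameter <= self.geometry.d * self.n_pillars / np.pi:
            raise ValidationError(
                f"ring diameter {self.ring_diameter} too small for "
                f"{self.n_pillars} non-overlapping pillars of diameter "
                f"{self.geometry.d}")
        if any(s <= 0 for s in self.psf_sigma):
            raise ValidationError("PSF sigmas must be > 0")
        if any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel sizes must be > 0")
        if self.noise_model not in ("gaussian", "poisson", "mixed", "none"):
            raise ValidationError(
                "noise_model must be gaussian, poisson, mixed or none")
        if self.amplitude <= 0 or self.background < 0:
            raise ValidationError("amplitude must be > 0 and background >= 0")

    @property
    def snr(self) -> float:
        """Peak signal-to-noise ratio: amplitude over the total noise
        standard deviation at a bright voxel (shot noise of signal plus
        background, plus Gaussian read noise where applicable)."""
        shot = (self.amplitude + self.background
                if self.noise_model in ("poisson", "mixed") else 0.0)
        read = (self.read_sigma ** 2
                if self.noise_model in ("gaussian", "mixed") else 0.0)
        total = np.sqrt(shot + read)
        return float("inf") if total == 0 else self.amplitude / total

    @property
    def force_array(self) -> np.ndarray:
        f = np.broadcast_to(np.asarray(self.forces, dtype=float),
                            (self.n_pillars,))
        return np.array(f)


@dataclass(frozen=True)
class RenderTruth:
    """Renderer ground truth: applied forces and noiseless centrelines."""

    forces: np.ndarray
    ring_centre: tuple[float, float]
    before: list[Centerline]
    after: list[Centerline]
    tip_deflections: np.ndarray
    seed: int


def _render_stack(spec: RenderSpec, centre_xy: np.ndarray,
                  deflect: np.ndarray, rng: np.random.Generator
                  ) -> VoxelStack:
    """Render cylinders along (possibly bent) centrelines, blur, add noise.

    ``centre_xy`` has shape (n_pillars, 2) (base positions, µm) and
    ``deflect`` shape (n_slices, n_pillars, 2): per-slice lateral centreline
    offsets.
    """
    dz, dy, dx = spec.voxel_size
    L = spec.geometry.L
    n_z = int(np.floor(L / dz)) + 1
    extent = spec.ring_diameter + 2 * (spec.geometry.d + spec.margin)
    n_y = int(np.ceil(extent / dy))
    n_x = int(np.ceil(extent / dx))
    ys = np.arange(n_y) * dy
    xs = np.arange(n_x) * dx
    r = spec.geometry.d / 2.0
    img = np.zeros((n_z, n_y, n_x), dtype=float)
    for k in range(n_z):
        sl = img[k]
        for p in range(spec.n_pillars):
            cx = centre_xy[p, 0] + deflect[k, p, 0]
            cy = centre_xy[p, 1] + deflect[k, p, 1]
            # restrict the disk rasterisation to a local window
            ix0 = np.searchsorted(xs, cx - r - dx)
            ix1 = np.searchsorted(xs, cx + r + dx)
            iy0 = np.searchsorted(ys, cy - r - dy)
            iy1 = np.searchsorted(ys, cy + r + dy)
            dxg = xs[ix0:ix1] - cx
            dyg = ys[iy0:iy1] - cy
            disk = (dyg[:, None] ** 2 + dxg[None, :] ** 2) <= r ** 2
            sl[iy0:iy1, ix0:ix1][disk] = 1.0
    sigma_vox = (spec.psf_sigma[0] / dz, spec.psf_sigma[1] / dy,
                 spec.psf_sigma[2] / dx)
    img = gaussian_filter(img, sigma=sigma_vox, mode="constant")
    signal = spec.background + spec.amplitude * img
    if spec.noise_model == "none":
        noisy = signal
    elif spec.noise_model == "gaussian":
        noisy = signal + rng.normal(0.0, spec.read_sigma, size=signal.shape)
    elif spec.noise_model == "poisson":
        noisy = rng.poisson(signal).astype(float)
    else:  # mixed: shot noise plus Gaussian read noise
        noisy = (rng.poisson(signal).astype(float)
                 + rng.normal(0.0, spec.read_sigma, size=signal.shape))
    return VoxelStack(intensities=np.clip(noisy, 0.0, None),
                      voxel_size=spec.voxel_size)


def render_pillar_ring(spec: RenderSpec
                       ) -> tuple[VoxelStack, VoxelStack, RenderTruth]:
    """Render before/after stacks of a contracting pillar ring.

    The "before" stack holds straight vertical pillars evenly spaced on a
    ring; the "after" stack bends each pillar toward the ring centre with
    the Euler-beam profile for its applied force.  Ground-truth noiseless
    centrelines (sampled at the slice heights) and forces are returned.

    Raises
    ------
    ValidationError
        If pillar footprints would overlap before blurring.
    """
    forces = spec.force_array
    dz = spec.voxel_size[0]
    L = spec.geometry.L
    n_z = int(np.floor(L / dz)) + 1
    z = np.arange(n_z) * dz
    extent = spec.ring_diameter + 2 * (spec.geometry.d + spec.margin)
    c0 = extent / 2.0
    ring_centre = (c0, c0)
    angles = 2 * np.pi * np.arange(spec.n_pillars) / spec.n_pillars
    R_ring = spec.ring_diameter / 2.0
    base = np.stack([c0 + R_ring * np.cos(angles),
                     c0 + R_ring * np.sin(angles)], axis=1)

    # minimal pairwise base distance must exceed one pillar diameter
    if spec.n_pillars > 1:
        dists = np.linalg.norm(base[:, None] - base[None, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        if dists.min() <= spec.geometry.d:
            raise ValidationError(
                f"pillar footprints overlap: minimal spacing "
                f"{dists.min():.3f} µm <= diameter {spec.geometry.d} µm")

    unit_w = _unit_profile(z, spec.geometry)  # deflection per pN at heights z
    # inward unit vectors per pillar
    inward = -np.stack([np.cos(angles), np.sin(angles)], axis=1)
    defl_mag = unit_w[:, None] * forces[None, :]          # (n_z, n_p)
    deflect_after = defl_mag[:, :, None] * inward[None, :, :]
    deflect_before = np.zeros_like(deflect_after)

    rng = np.random.default_rng(spec.seed)
    before = _render_stack(spec, base, deflect_before, rng)
    after = _render_stack(spec, base, deflect_after, rng)

    truth_before = [Centerline(pillar_id=p + 1, z=z,
                               cx=np.full(n_z, base[p, 0]),
                               cy=np.full(n_z, base[p, 1]))
                    for p in range(spec.n_pillars)]
    truth_after = [Centerline(pillar_id=p + 1, z=z,
                              cx=base[p, 0] + deflect_after[:, p, 0],
                              cy=base[p, 1] + deflect_after[:, p, 1])
                   for p in range(spec.n_pillars)]
    truth = RenderTruth(forces=forces, ring_centre=ring_centre,
                        before=truth_before, after=truth_after,
                        tip_deflections=unit_w[-1] * forces, seed=spec.seed)
    return before, after, truth


def gen_calibration_series(slope: float = 3000.0,
                           intercept: float = 50.0,
                           levels: Sequence[float] = (0.001, 0.01, 0.1, 1.0),
                           sigma: float = 10.0,
                           seed: int = 0,
                           n_fields: int = 5
                           ) -> tuple[CalibrationSeries, dict]:
    """Noisy linear dilution series with its generating parameters.

    Intensities are ``slope·C + intercept`` plus i.i.d. Gaussian noise of
    standard deviation ``sigma``; the default levels span the dilution range
    0.001–1 µM.  Returns ``(series, truth)`` where ``truth`` records the
    generating slope, intercept, noise level and seed.
    """
    levels = np.asarray(levels, dtype=float)
    if len(levels) < 3:
        raise ValidationError("need at least 3 concentration levels")
    rng = np.random.default_rng(seed)
    intensity = slope * levels + intercept + rng.normal(0, sigma, len(levels))
    series = CalibrationSeries(concentration=levels,
                               mean_intensity=np.clip(intensity, 0, None),
                               n_fields=np.full(len(levels), n_fields))
    truth = {"slope": slope, "intercept": intercept, "sigma": sigma,
             "seed": seed}
    return series, truth
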