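"""One-dimensional viscoelastic model of actomyosin contraction on elastic micropillars.

A ring of elastic pillars (spring constant ``k_p``) is coated with a
crosslinked actomyosin network, idealised as an elastic spring ``k_am`` in
parallel with a dashpot ``gamma_am``.  Myofilaments from a pool of size
``N_m`` transiently bind the actin network; each bound filament contributes a
contractile force ``f_s``, so the active force pulling the pillar tips toward
the ring centre is ``F_A = n_b * f_s``.  The tip displacement ``x`` obeys the
overdamped force balance

    gamma_am * dx/dt = F_A - (k_p + k_am) * x

and the bound fraction evolves by first-order binding kinetics

    dn_b/dt = k_on * (N_m - n_b) - k_off * n_b.

Two feedback variants are implemented, selected by ``ModelParameters.mode``:

``load_dependent``
    The unbinding rate falls with the per-filament load ``f`` (catch-bond-like
    behaviour), ``k_off(f) = k_off0 * exp(-f / f_d)`` with
    ``f = (k_p + k_am) * x / max(n_b, eps)``.  Load stabilises engagement,
    giving positive feedback between stress build-up and motor recruitment:
    an accelerating then decelerating contraction, and a steady-state force
    that is nearly independent of pillar stiffness.

``density_only``
    The control variant in which all feedback enters through the actin
    density instead.  As the network contracts toward the ring centre the
    actin densifies, ``rho(x) = rho0 * R / (R - x)``; both the contractile
    force per bound filament and the binding rate scale with ``rho/rho0``
    while unbinding is load-independent (``k_off = k_off0``).  This variant
    predicts a stronger (and different) stiffness dependence of the
    steady-state force than the load-dependent model.

Units are pN, µm and s throughout; mechanical power is converted to watts
only at output (1 pN·µm/s = 1e-18 W).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import IntegrationError, ValidationError

__all__ = [
    "ModelParameters",
    "ModelState",
    "ParameterSchedule",
    "Trajectory",
    "SteadyState",
    "REFERENCE_PARAMETERS",
    "simulate_contraction",
    "steady_state",
    "peak_velocity",
    "mechanical_power",
    "density_only_force",
    "active_work",
]

#: conversion factor from pN·µm/s to W
PW_PER_PN_UM_S = 1e-18

#: regulariser for the per-filament load at n_b -> 0
_EPS_NB = 1e-6

_MODES = ("load_dependent", "density_only")


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of the 1D contractility model (units: pN, µm, s).

    Attributes
    ----------
    k_p : float
        Pillar spring constant (pN/µm).
    k_am : float
        Actomyosin network spring constant (pN/µm).
    gamma_am : float
        Network friction coefficient (pN·s/µm); sets the slow stress
        build-up timescale ``gamma_am / (k_p + k_am)``.
    N_m : float
        Available myofilament pool per pillar (dimensionless count).
    f_s : float
        Contractile force per bound myofilament (pN).
    k_on0 : float
        Baseline binding rate (1/s).
    k_off0 : float
        Unbinding rate at zero load (1/s).
    f_d : float
        Load scale of unbinding suppression (pN); only used in
        ``load_dependent`` mode.
    rho0 : float
        Reference actin areal density (normalised; only the ratio
        ``rho/rho0`` enters the equations).
    R : float
        Pillar-ring radius at tip height (µm); sets the densification scale
        in ``density_only`` mode.
    mode : str
        ``"load_dependent"`` or ``"density_only"``.
    n_pillars : int
        Number of pillars in the ring (used for ring-level power).
    """

    k_p: float
    k_am: float = 1.0
    gamma_am: float = 2000.0
    N_m: float = 10.0
    f_s: float = 40.0
    k_on0: float = 0.05
    k_off0: float = 1.0
    f_d: float = 10.0
    rho0: float = 1.0
    R: float = 13.0
    mode: str = "load_dependent"
    n_pillars: int = 10

    def __post_init__(self) -> None:
        positive = {"k_p": self.k_p, "gamma_am": self.gamma_am, "f_d": self.f_d,
                    "rho0": self.rho0, "R": self.R}
        for name, value in positive.items():
            if not np.isfinite(value) or value <= 0:
                raise ValidationError(f"{name} must be finite and > 0, got {value!r}")
        nonneg = {"k_am": self.k_am, "N_m": self.N_m, "f_s": self.f_s,
                  "k_on0": self.k_on0, "k_off0": self.k_off0}
        for name, value in nonneg.items():
            if not np.isfinite(value) or value < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {value!r}")
        if self.mode not in _MODES:
            raise ValidationError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.n_pillars < 1:
            raise ValidationError(f"n_pillars must be >= 1, got {self.n_pillars}")

    def replace(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given fields overridden (re-validated)."""
        valid = {f.name for f in dataclasses.fields(self)}
        unknown = set(overrides) - valid
        if unknown:
            raise ValidationError(f"unknown parameter override(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    @property
    def n_b_unloaded(self) -> float:
        """Zero-load binding equilibrium ``k_on0*N_m/(k_on0+k_off0)``."""
        denom = self.k_on0 + self.k_off0
        if denom == 0:
            return 0.0
        return self.k_on0 * self.N_m / denom


#: Reference parameter set used throughout the package documentation and
#: tests.  It is a documented default, not a measurement: chosen so that at
#: k_p = 35 pN/µm the steady-state pillar force is of order 10² pN and the
#: time to peak contraction velocity is of order one minute.
REFERENCE_PARAMETERS = ModelParameters(k_p=35.0)


@dataclass(frozen=True)
class ModelState:
    """Instantaneous model state: time, tip displacement and bound motors."""

    t: float
    x: float
    n_b: float


@dataclass(frozen=True)
class ParameterSchedule:
    """Piecewise-constant parameter changes during a simulation.

    ``switches`` is an ordered sequence of ``(switch_time, overrides)`` pairs
    where ``overrides`` is a dict of ModelParameters field names.  The
    integrator restarts exactly at each switch time, so e.g. an ATP washout
    is modelled by ``(300.0, {"k_on0": 0.0})``.

    ``initial_binding`` selects the initial bound fraction: ``"unloaded"``
    starts from the zero-load binding equilibrium (motors present before
    activation), ``"preloaded"`` starts from the steady-state bound number,
    which responds more rapidly.
    """

    switches: Sequence[tuple[float, dict]] = ()
    initial_binding: str = "unloaded"

    def __post_init__(self) -> None:
        if self.initial_binding not in ("unloaded", "preloaded"):
            raise ValidationError(
                f"initial_binding must be 'unloaded' or 'preloaded', "
                f"got {self.initial_binding!r}")
        times = [t for t, _ in self.switches]
        if any(not np.isfinite(t) or t <= 0 for t in times):
            raise ValidationError("switch times must be finite and > 0")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("switch times must be strictly increasing")
        param_names = {f.name for f in dataclasses.fields(ModelParameters)}
        for t, overrides in self.switches:
            unknown = set(overrides) - param_names
            if unknown:
                raise ValidationError(
                    f"schedule at t={t}: unknown parameter(s) {sorted(unknown)}")

    def segments(self, params: ModelParameters, t_end: float
                 ) -> Iterator[tuple[float, float, ModelParameters]]:
        """Yield ``(t0, t1, params)`` integration segments covering [0, t_end]."""
        current = params
        t0 = 0.0
        for t_switch, overrides in self.switches:
            if t_switch >= t_end:
                break
            if t_switch > t0:
                yield t0, t_switch, current
            current = current.replace(**overrides)
            t0 = t_switch
        if t0 < t_end:
            yield t0, t_end, current


@dataclass(frozen=True)
class Trajectory:
    """Time series of a simulated (or observed) contraction.

    All arrays share the same length; ``F_pillar = k_p * x`` exactly by
    construction and ``P = n_pillars * F_pillar * v`` in watts.
    """

    t: np.ndarray
    x: np.ndarray
    v: np.ndarray
    n_b: np.ndarray
    F_A: np.ndarray
    F_pillar: np.ndarray
    n_pillars: int = 1

    def __post_init__(self) -> None:
        arrays = (self.t, self.x, self.v, self.n_b, self.F_A, self.F_pillar)
        n = len(self.t)
        if n == 0:
            raise ValidationError("trajectory must contain at least one sample")
        if any(len(a) != n for a in arrays):
            raise ValidationError("trajectory series must have equal lengths")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("trajectory times must be strictly increasing")

    @property
    def P(self) -> np.ndarray:
        """Ring-level instantaneous mechanical power (W)."""
        return self.n_pillars * self.F_pillar * self.v * PW_PER_PN_UM_S

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self):
        """Return the trajectory as a pandas DataFrame with unit-suffixed headers."""
        import pandas as pd

        return pd.DataFrame({
            "t_s": self.t, "x_um": self.x, "v_um_per_s": self.v,
            "n_b": self.n_b, "F_A_pN": self.F_A,
            "F_pillar_pN": self.F_pillar, "P_W": self.P,
        })


@dataclass(frozen=True)
class SteadyState:
    """Fixed point of the contraction dynamics."""

    x: float
    n_b: float
    F_pillar: float
    degenerate: bool = False


def _densification(x: float | np.ndarray, params: ModelParameters):
    """rho(x)/rho0 = R / (R - x); diverges as the tips reach the centre."""
    return params.R / (params.R - x)


def density_only_force(params: ModelParameters, state: ModelState) -> float:
    """Active force in the density-only variant, ``n_b * f_s * rho(x)/rho0``.

    Raises
    ------
    ValidationError
        If ``state.x >= R`` (the densification factor diverges).
    """
    if params.mode != "density_only":
        raise ValidationError("density_only_force requires mode='density_only'")
    if state.x >= params.R:
        raise ValidationError(
            f"x = {state.x} µm >= ring radius R = {params.R} µm: "
            "densification factor diverges")
    return state.n_b * params.f_s * _densification(state.x, params)


def _rhs(t: float, y: np.ndarray, p: ModelParameters) -> tuple[float, float]:
    x, n_b = y
    stiff = p.k_p + p.k_am
    if p.mode == "load_dependent":
        F_A = n_b * p.f_s
        load = stiff * x / max(n_b, _EPS_NB)
        k_off = p.k_off0 * np.exp(-load / p.f_d)
        k_on = p.k_on0
    else:  # density_only: both force and binding scale with actin density
        # guard trial steps that overshoot the singularity at x = R
        rho = p.R / max(p.R - x, p.R * 1e-12)
        F_A = n_b * p.f_s * rho
        k_off = p.k_off0
        k_on = p.k_on0 * rho
    v = (F_A - stiff * x) / p.gamma_am
    dn_b = k_on * (p.N_m - n_b) - k_off * n_b
    return v, dn_b


def _derived_series(x: np.ndarray, n_b: np.ndarray, p: ModelParameters
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    stiff = p.k_p + p.k_am
    if p.mode == "load_dependent":
        F_A = n_b * p.f_s
    else:
        F_A = n_b * p.f_s * _densification(x, p)
    v = (F_A - stiff * x) / p.gamma_am
    return v, F_A, p.k_p * x


def simulate_contraction(params: ModelParameters,
                         schedule: ParameterSchedule | None = None,
                         t_end: float = 600.0,
                         dt_out: float = 1.0,
                         rtol: float = 1e-8,
                         atol: float = 1e-10) -> Trajectory:
    """Integrate the contraction dynamics and sample the solution at ``dt_out``.

    The system is moderately stiff (fast binding kinetics against slow
    viscoelastic stress build-up), so an adaptive stiffness-switching solver
    (LSODA) is used.  Integration restarts exactly at every schedule switch
    time, carrying the state across the discontinuity.

    Parameters
    ----------
    params : ModelParameters
        Model parameters; ``params.mode`` selects the feedback variant.
    schedule : ParameterSchedule, optional
        Piecewise parameter overrides and the initial binding condition.
    t_end : float
        Duration of the simulation (s).
    dt_out : float
        Output sampling interval (s).

    Returns
    -------
    Trajectory
        Sampled at ``0, dt_out, 2*dt_out, ... <= t_end`` (switch times are
        additionally included as output samples).

    Raises
    ------
    IntegrationError
        If the solver fails or produces a non-finite state; the error names
        the offending time.
    """
    if not (np.isfinite(t_end) and t_end > 0):
        raise ValidationError(f"t_end must be finite and > 0, got {t_end!r}")
    if not (np.isfinite(dt_out) and dt_out > 0):
        raise ValidationError(f"dt_out must be finite and > 0, got {dt_out!r}")
    if schedule is None:
        schedule = ParameterSchedule()

    if schedule.initial_binding == "preloaded":
        ss = steady_state(params)
        y = np.array([0.0, ss.n_b])
    else:
        y = np.array([0.0, params.n_b_unloaded])

    grid = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    grid = grid[grid <= t_end]
    switch_times = np.array([t for t, _ in schedule.switches if t < t_end])
    out_t = np.unique(np.concatenate([grid, switch_times]))

    ts: list[np.ndarray] = []
    xs: list[np.ndarray] = []
    nbs: list[np.ndarray] = []
    vs: list[np.ndarray] = []
    fas: list[np.ndarray] = []
    fps: list[np.ndarray] = []
    first_segment = True
    for t0, t1, seg_params in schedule.segments(params, t_end):
        t_eval = out_t[(out_t >= t0) & (out_t <= t1)]
        # always evaluate the segment endpoint so the restart state is exact
        t_eval = np.unique(np.append(t_eval, t1))
        events = None
        if seg_params.mode == "density_only":
            # the densification law is singular at x = R; stop early rather
            # than letting the integrator grind toward the singularity
            def _hit_centre(t, yy, p=seg_params):
                if not np.isfinite(yy[0]):
                    return -1.0
                return p.R * (1.0 - 1e-6) - yy[0]
            _hit_centre.terminal = True
            events = [_hit_centre]
        sol = solve_ivp(_rhs, (t0, t1), y, method="LSODA", args=(seg_params,),
                        t_eval=t_eval, rtol=rtol, atol=atol, events=events)
        if sol.status == 1:  # terminated by the singularity event
            raise IntegrationError(
                f"tip reached the ring centre (x -> R) at "
                f"t = {sol.t_events[0][0]:g} s: runaway densification")
        if not sol.success:
            raise IntegrationError(
                f"integration failed near t = {sol.t[-1] if len(sol.t) else t0:g} s: "
                f"{sol.message}")
        if not np.all(np.isfinite(sol.y)):
            bad = sol.t[np.argmax(~np.isfinite(sol.y).all(axis=0))]
            raise IntegrationError(f"non-finite state at t = {bad:g} s")
        y = sol.y[:, -1].copy()
        # keep only requested output samples; drop the duplicated segment start
        emit = np.isin(sol.t, out_t)
        if not first_segment:
            emit &= sol.t > t0
        x_seg, nb_seg = sol.y[0][emit], sol.y[1][emit]
        # clip binding round-off so 0 <= n_b <= N_m holds exactly at output
        nb_seg = np.clip(nb_seg, 0.0, seg_params.N_m)
        v_seg, fa_seg, fp_seg = _derived_series(x_seg, nb_seg, seg_params)
        ts.append(sol.t[emit]); xs.append(x_seg); nbs.append(nb_seg)
        vs.append(v_seg); fas.append(fa_seg); fps.append(fp_seg)
        first_segment = False

    return Trajectory(
        t=np.concatenate(ts), x=np.concatenate(xs), v=np.concatenate(vs),
        n_b=np.concatenate(nbs), F_A=np.concatenate(fas),
        F_pillar=np.concatenate(fps), n_pillars=params.n_pillars)


def steady_state(params: ModelParameters) -> SteadyState:
    """Find the fixed point of the contraction dynamics by root finding.

    In ``load_dependent`` mode the force balance pins the per-filament load
    at exactly ``f_s`` at any fixed point with ``n_b > 0``, so the binding
    balance reduces to a one-dimensional root problem in ``n_b`` which is
    bracketed and solved on ``(0, N_m]``.  In ``density_only`` mode the root
    problem is solved in ``x`` on ``[0, R)``.

    Returns the zero state flagged ``degenerate=True`` when no positive fixed
    point exists (no motors, no binding, or — in density-only mode — a
    runaway contraction with no balance point short of the ring centre).
    """
    stiff = params.k_p + params.k_am
    if params.N_m == 0 or params.f_s == 0 or params.k_on0 == 0:
        return SteadyState(0.0, params.n_b_unloaded if params.f_s == 0 else 0.0,
                           0.0, degenerate=True)

    if params.mode == "load_dependent":
        k_off_ss = params.k_off0 * np.exp(-params.f_s / params.f_d)

        def binding_balance(n_b: float) -> float:
            return params.k_on0 * (params.N_m - n_b) - k_off_ss * n_b

        lo, hi = 1e-12, params.N_m
        if binding_balance(hi) >= 0:
            n_b_ss = params.N_m
        else:
            n_b_ss = brentq(binding_balance, lo, hi, xtol=1e-14, rtol=1e-15)
        x_ss = n_b_ss * params.f_s / stiff
        return SteadyState(x_ss, n_b_ss, params.k_p * x_ss)

    # density_only: solve the force balance in x with n_b at its
    # density-dependent binding equilibrium
    def residual(x: float) -> float:
        rho = _densification(x, params)
        k_on = params.k_on0 * rho
        n_b = params.N_m * k_on / (k_on + params.k_off0)
        return n_b * params.f_s * rho - stiff * x

    # the densification diverges at x -> R, so the residual is positive at
    # both ends whenever a balance exists; bracket the first (stable)
    # crossing from positive to negative by scanning
    x_hi = params.R * (1.0 - 1e-9)
    xs = np.linspace(0.0, x_hi, 4096)
    vals = np.array([residual(x) for x in xs])
    crossings = np.nonzero((vals[:-1] > 0) & (vals[1:] <= 0))[0]
    if len(crossings) == 0:  # runaway: active force wins up to the centre
        return SteadyState(0.0, 0.0, 0.0, degenerate=True)
    i = crossings[0]
    x_ss = brentq(residual, xs[i], xs[i + 1], xtol=1e-13)
    rho = _densification(x_ss, params)
    k_on = params.k_on0 * rho
    n_b_ss = params.N_m * k_on / (k_on + params.k_off0)
    return SteadyState(x_ss, n_b_ss, params.k_p * x_ss)


def peak_velocity(traj: Trajectory) -> tuple[float, float]:
    """Return ``(v_max, t_at_vmax)``; ties broken by the earliest time."""
    i = int(np.argmax(traj.v))
    return float(traj.v[i]), float(traj.t[i])


def mechanical_power(traj: Trajectory, n_pillars: int | None = None
                     ) -> tuple[np.ndarray, float]:
    """Ring-level mechanical power ``P(t) = n_pillars * F_pillar * v`` in W.

    Returns ``(P_series, P_peak)``.  ``n_pillars`` defaults to the
    trajectory's own pillar count.
    """
    n = traj.n_pillars if n_pillars is None else n_pillars
    P = n * traj.F_pillar * traj.v * PW_PER_PN_UM_S
    return P, float(np.max(P))


def active_work(traj: Trajectory, n_pillars: int | None = None) -> np.ndarray:
    """Cumulative work done by the active force, ``∫ n F_A v dt`` (W·s = J).

    Exceeds the stored elastic energy ``n * k_p x²/2`` whenever the dashpot
    dissipates (``gamma_am > 0``).
    """
    n = traj.n_pillars if n_pillars is None else n_pillars
    p_active = n * traj.F_A * traj.v * PW_PER_PN_UM_S
    out = np.zeros_like(traj.t)
    out[1:] = np.cumsum(0.5 * (p_active[1:] + p_active[:-1]) * np.diff(traj.t))
    return out
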