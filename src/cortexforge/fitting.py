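"""Calibration of the contractility model to a measured contraction curve.

The protocol is "fit once, predict everywhere": a subset of model
parameters is constrained by bounded nonlinear least squares against a
single pillar-tip displacement trajectory at one known pillar stiffness,
then the calibrated model predicts steady-state forces and peak velocities
across the whole stiffness range.

By default the free set is {gamma_am, f_d, n_m_f_s, k_off0}, where
``n_m_f_s`` is the lumped active amplitude ``N_m·f_s``: pool size and
per-filament force are not separately identifiable from a single
displacement curve, so the product is fitted with ``N_m`` held at its
configured value.  Optimisation runs in log10 parameter space (all free
parameters are positive scale parameters) from seeded Latin-hypercube
starts; approximate standard errors come from the Gauss-Newton quadratic
expansion of the loss at the optimum, and a warning is issued instead when
the expansion is too ill-conditioned to be meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .errors import FitError, ValidationError
from .model import (ModelParameters, Trajectory, peak_velocity,
                    simulate_contraction, steady_state)

__all__ = ["FitSpec", "FitResult", "fit_model_to_trajectory",
           "predict_across_stiffness"]

#: parameters that may be fitted; ``n_m_f_s`` is the lumped product N_m*f_s
_FITTABLE = ("gamma_am", "k_am", "N_m", "f_s", "n_m_f_s", "f_d", "k_on0",
             "k_off0")

_DEFAULT_BOUNDS = {
    "gamma_am": (100.0, 1e5),
    "k_am": (1e-3, 50.0),
    "N_m": (1.0, 1e3),
    "f_s": (1.0, 200.0),
    "n_m_f_s": (10.0, 1e4),
    "f_d": (0.5, 500.0),
    "k_on0": (1e-4, 10.0),
    "k_off0": (1e-3, 100.0),
}

_LOSSES = ("sse_displacement", "sse_displacement_plus_velocity")


@dataclass(frozen=True)
class FitSpec:
    """What to fit, within which bounds, and how."""

    free: tuple[str, ...] = ("gamma_am", "f_d", "n_m_f_s", "k_off0")
    bounds: dict = field(default_factory=dict)
    loss: str = "sse_displacement"
    n_starts: int = 5
    seed: int = 0
    extra_starts: Sequence[dict] = ()

    def __post_init__(self) -> None:
        unknown = set(self.free) - set(_FITTABLE)
        if unknown:
            raise ValidationError(f"not fittable: {sorted(unknown)}; "
                                  f"choose from {_FITTABLE}")
        if "n_m_f_s" in self.free and ({"N_m", "f_s"} & set(self.free)):
            raise ValidationError(
                "n_m_f_s is the lumped product N_m*f_s and cannot be fitted "
                "together with N_m or f_s")
        if len(set(self.free)) != len(self.free):
            raise ValidationError("duplicate free parameters")
        if self.loss not in _LOSSES:
            raise ValidationError(f"loss must be one of {_LOSSES}")
        if self.n_starts < 1:
            raise ValidationError("n_starts must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if name not in _FITTABLE:
                raise ValidationError(f"bounds given for unknown parameter {name}")
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
                raise ValidationError(
                    f"bounds for {name} must be finite with 0 < lower < upper")

    def bounds_for(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, _DEFAULT_BOUNDS[name])


@dataclass(frozen=True)
class FitResult:
    """Outcome of a trajectory fit."""

    params: ModelParameters
    free_values: dict
    loss: float
    standard_errors: dict
    converged: bool
    n_fev: int
    at_bounds: dict
    condition_number: float

    @property
    def any_boundary(self) -> bool:
        return any(self.at_bounds.values())


def _apply_free(base: ModelParameters, names: Sequence[str],
                values: np.ndarray) -> ModelParameters:
    over = {}
    for name, v in zip(names, values):
        if name == "n_m_f_s":
            over["f_s"] = v / base.N_m
        else:
            over[name] = v
    return base.replace(**over)


def _residuals(theta_log: np.ndarray, names, base, t, x_obs, v_obs, loss,
               dt_out) -> np.ndarray:
    values = 10.0 ** theta_log
    try:
        params = _apply_free(base, names, values)
        traj = simulate_contraction(params, t_end=float(t[-1]), dt_out=dt_out)
    except Exception:
        return np.full(len(t) * (2 if v_obs is not None else 1), 1e6)
    x_model = np.interp(t, traj.t, traj.x)
    res = x_model - x_obs
    if v_obs is not None:
        v_model = np.gradient(x_model, t)
        res = np.concatenate([res, v_model - v_obs])
    return res


def fit_model_to_trajectory(observed: Trajectory,
                            spec: FitSpec,
                            k_p: float,
                            base_params: Optional[ModelParameters] = None
                            ) -> FitResult:
    """Fit free model parameters to an observed (t, x) contraction curve.

    Parameters
    ----------
    observed : Trajectory
        Only ``t`` and ``x`` are used.
    k_p : float
        Pillar stiffness (pN/µm), known from geometry — never fitted.
    base_params : ModelParameters, optional
        Values for every fixed parameter (defaults to the reference set with
        the given ``k_p``).

    Raises
    ------
    FitError
        If no start converges (never a silent best effort).
    """
    if len(observed) < 10:
        raise ValidationError("need at least 10 observed samples")
    if base_params is None:
        from .model import REFERENCE_PARAMETERS
        base_params = REFERENCE_PARAMETERS
    base_params = base_params.replace(k_p=float(k_p))

    t = np.asarray(observed.t, dtype=float)
    x_obs = np.asarray(observed.x, dtype=float)
    v_obs = (np.gradient(x_obs, t)
             if spec.loss == "sse_displacement_plus_velocity" else None)
    dt_out = float(np.min(np.diff(t)))

    names = spec.free
    log_lo = np.array([np.log10(spec.bounds_for(n)[0]) for n in names])
    log_hi = np.array([np.log10(spec.bounds_for(n)[1]) for n in names])

    sampler = qmc.LatinHypercube(d=len(names), seed=spec.seed)
    starts = log_lo + sampler.random(spec.n_starts) * (log_hi - log_lo)
    for extra in spec.extra_starts:
        vals = []
        for n in names:
            if n not in extra:
                raise ValidationError(f"extra start missing parameter {n}")
            vals.append(np.log10(extra[n]))
        starts = np.vstack([starts, vals])

    args = (names, base_params, t, x_obs, v_obs, spec.loss, dt_out)
    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, log_lo, log_hi)
        try:
            sol = least_squares(_residuals, theta0, bounds=(log_lo, log_hi),
                                args=args, method="trf", xtol=1e-12,
                                ftol=1e-14, gtol=1e-12)
        except Exception:
            continue
        if not sol.success:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("no multistart converged")

    values = 10.0 ** best.x
    fitted = _apply_free(base_params, names, values)
    loss = 2.0 * best.cost  # least_squares cost is SSE/2

    # Gauss-Newton covariance in log10 space, mapped to natural scale
    J = best.jac
    n_res = len(best.fun)
    dof = max(n_res - len(names), 1)
    s2 = loss / dof
    JTJ = J.T @ J
    cond = float(np.linalg.cond(JTJ)) if JTJ.size else 0.0
    se = {}
    if cond > 1e8 or not np.isfinite(cond):
        warnings.warn(
            f"loss Hessian condition number {cond:.2e} exceeds 1e8: the fit "
            "has sloppy directions and standard errors are not reported",
            RuntimeWarning)
        se = {n: np.nan for n in names}
    else:
        cov_log = s2 * np.linalg.inv(JTJ)
        # d(value)/d(log10 value) = value * ln(10)
        for i, n in enumerate(names):
            se[n] = float(np.sqrt(max(cov_log[i, i], 0.0))
                          * values[i] * np.log(10.0))

    rel = 1e-3
    at_bounds = {
        n: bool(best.x[i] <= log_lo[i] + rel * (log_hi[i] - log_lo[i])
                or best.x[i] >= log_hi[i] - rel * (log_hi[i] - log_lo[i]))
        for i, n in enumerate(names)}

    return FitResult(params=fitted,
                     free_values={n: float(v) for n, v in zip(names, values)},
                     loss=float(loss), standard_errors=se, converged=True,
                     n_fev=int(best.nfev), at_bounds=at_bounds,
                     condition_number=cond)


def predict_across_stiffness(fit: FitResult | ModelParameters,
                             k_p_grid: Sequence[float],
                             t_end: float = 600.0,
                             dt_out: float = 1.0):
    """Predict steady-state force and peak velocity across pillar stiffness.

    For each stiffness on the grid the calibrated model is re-run (all other
    parameters fixed from the fit) and the steady state and velocity peak
    are recorded.  Grid points whose integration fails are reported as NaN
    rows; the remaining points are still returned.

    Returns
    -------
    pandas.DataFrame
        Columns ``k_p``, ``F_pillar_ss``, ``v_max``, ``t_at_vmax``.
    """
    import pandas as pd

    params = fit.params if isinstance(fit, FitResult) else fit
    rows = []
    for k_p in k_p_grid:
        p = params.replace(k_p=float(k_p))
        try:
            ss = steady_state(p)
            traj = simulate_contraction(p, t_end=t_end, dt_out=dt_out)
            v_max, t_at = peak_velocity(traj)
            rows.append((k_p, ss.F_pillar, v_max, t_at))
        except Exception:
            rows.append((k_p, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["k_p", "F_pillar_ss", "v_max",
                                       "t_at_vmax"])
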