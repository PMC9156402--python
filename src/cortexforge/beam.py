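"""Euler–Bernoulli cantilever mechanics for force inference from pillar bending.

A hydrogel pillar is modelled as a slender cantilever of circular cross
section (length ``L``, diameter ``d``, Young's modulus ``E``) clamped at the
substrate.  A horizontal point load ``F`` applied at height ``a`` (default:
the tip) produces the classic cubic deflection profile

    w(z) = F z² (3a − z) / (6 E I)          for z ≤ a
    w(z) = F a² (3z − a) / (6 E I)          for z > a,

with second moment of area ``I = π d⁴ / 64`` and tip stiffness
``k_p = 3 E I / L³`` when ``a = L``.  Because ``w`` is linear in ``F``, the
inverse problem — recovering the force from a measured centreline profile —
is a one-parameter linear least-squares fit with a closed-form solution.

Profile samples below ``foot_cutoff`` (default 2 µm) are excluded from fits:
printed pillars have a stiffer foot that is hardly deflected, so the ideal
cantilever model does not apply there.  Deflections are signed, positive
toward the ring centre.  Units: µm, pN, and kPa for the modulus
(1 kPa = 1000 pN/µm²).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "PillarGeometry",
    "DeflectionProfile",
    "second_moment",
    "pillar_stiffness",
    "predict_profile",
    "fit_force",
    "shear_strain",
]

#: pN/µm² per kPa
PN_PER_UM2_PER_KPA = 1000.0


@dataclass(frozen=True)
class PillarGeometry:
    """Cantilever geometry and material.

    Attributes
    ----------
    L : float
        Pillar length (µm).
    d : float
        Cross-section diameter (µm), circular.
    E_kPa : float
        Young's modulus in kPa.
    foot_cutoff : float
        Height below which profile data are ignored in fits (µm).
    attach_height : float or None
        Height of network attachment ``a`` (µm); ``None`` means the tip.
    """

    L: float
    d: float
    E_kPa: float
    foot_cutoff: float = 2.0
    attach_height: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.d < self.L):
            raise ValidationError(f"require 0 < d < L, got d={self.d}, L={self.L}")
        if self.E_kPa <= 0:
            raise ValidationError(f"E_kPa must be > 0, got {self.E_kPa}")
        a = self.a
        if not (0 <= self.foot_cutoff < a <= self.L):
            raise ValidationError(
                f"require 0 <= foot_cutoff < attach_height <= L, got "
                f"foot_cutoff={self.foot_cutoff}, a={a}, L={self.L}")

    @property
    def a(self) -> float:
        """Load application height (µm); defaults to the tip."""
        return self.L if self.attach_height is None else self.attach_height

    @property
    def E(self) -> float:
        """Young's modulus in pN/µm²."""
        return self.E_kPa * PN_PER_UM2_PER_KPA


@dataclass(frozen=True)
class DeflectionProfile:
    """Lateral centreline displacement versus height above the substrate."""

    z: np.ndarray
    w: np.ndarray
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "w", w)
        if z.shape != w.shape or z.ndim != 1:
            raise ValidationError("z and w must be 1D arrays of equal length")
        if np.any(np.diff(z) <= 0):
            raise ValidationError("profile heights must be strictly increasing")
        if np.any(z < 0):
            raise ValidationError("profile heights must be non-negative")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != z.shape or np.any(s <= 0):
                raise ValidationError("sigma must match z and be strictly positive")

    def __len__(self) -> int:
        return len(self.z)


def second_moment(geom: PillarGeometry) -> float:
    """Second moment of area of the circular cross-section, ``π d⁴ / 64`` (µm⁴)."""
    return np.pi * geom.d ** 4 / 64.0


def pillar_stiffness(geom: PillarGeometry) -> float:
    """Cantilever tip stiffness ``k_p = 3 E I / L³`` (pN/µm)."""
    return 3.0 * geom.E * second_moment(geom) / geom.L ** 3


def _unit_profile(z: np.ndarray, geom: PillarGeometry) -> np.ndarray:
    """Deflection profile for a unit (1 pN) point load at the attach height."""
    a = geom.a
    EI = geom.E * second_moment(geom)
    z = np.asarray(z, dtype=float)
    below = z <= a
    w = np.empty_like(z)
    w[below] = z[below] ** 2 * (3.0 * a - z[below]) / (6.0 * EI)
    w[~below] = a ** 2 * (3.0 * z[~below] - a) / (6.0 * EI)
    return w


def predict_profile(geom: PillarGeometry, F: float,
                    z: Optional[np.ndarray] = None) -> DeflectionProfile:
    """Predict the deflection profile under a point load ``F`` (pN).

    Parameters
    ----------
    z : array, optional
        Heights at which to evaluate (µm); defaults to 31 evenly spaced
        points on ``[0, L]``.
    """
    if not np.isfinite(F):
        raise ValidationError(f"F must be finite, got {F!r}")
    if z is None:
        z = np.linspace(0.0, geom.L, 31)
    return DeflectionProfile(z=np.asarray(z, dtype=float),
                             w=F * _unit_profile(z, geom))


def _fit_single_force(profile: DeflectionProfile, geom: PillarGeometry
                      ) -> tuple[float, float]:
    """Closed-form linear least squares for the load amplitude.

    Returns ``(F_hat, residual_rms)`` using samples at ``z >= foot_cutoff``;
    weighted by ``1/sigma²`` when per-sample uncertainties are present.
    """
    mask = profile.z >= geom.foot_cutoff
    if np.count_nonzero(mask) < 3:
        raise InsufficientDataError(
            f"need >= 3 samples at z >= foot_cutoff = {geom.foot_cutoff} µm, "
            f"got {int(np.count_nonzero(mask))}")
    z, w = profile.z[mask], profile.w[mask]
    s = _unit_profile(z, geom)
    if profile.sigma is not None:
        wt = 1.0 / profile.sigma[mask] ** 2
    else:
        wt = np.ones_like(z)
    denom = np.sum(wt * s * s)
    if denom == 0:
        raise InsufficientDataError("degenerate design: unit profile vanishes "
                                    "at every retained sample")
    F_hat = float(np.sum(wt * s * w) / denom)
    resid = w - F_hat * s
    return F_hat, float(np.sqrt(np.mean(resid ** 2)))


def fit_force(measured: DeflectionProfile,
              initial: Optional[DeflectionProfile] = None,
              geom: PillarGeometry = None,
              subtract_raw: bool = False) -> tuple[float, float]:
    """Infer the active force from a measured deflection profile.

    A one-parameter least-squares fit of the Euler-beam shape to the
    measured profile, restricted to heights above the foot cutoff.  When a
    pre-contraction profile ``initial`` is supplied (pillars are not always
    perfectly straight before activation), a force ``F0`` is first fitted to
    it and its *predicted* shape subtracted from the measurement before the
    final fit; pass ``subtract_raw=True`` to subtract the raw initial
    samples instead (requires matching heights).

    Returns
    -------
    (F_hat, residual_rms)
        Fitted force (pN) and root-mean-square residual (µm) over the
        retained samples.
    """
    if geom is None:
        raise ValidationError("geom is required")
    if initial is not None:
        if subtract_raw:
            if len(initial) != len(measured) or not np.allclose(
                    initial.z, measured.z):
                raise ValidationError(
                    "raw subtraction requires matching sample heights")
            corrected = DeflectionProfile(z=measured.z,
                                          w=measured.w - initial.w,
                                          sigma=measured.sigma)
        else:
            F0, _ = _fit_single_force(initial, geom)
            corrected = DeflectionProfile(
                z=measured.z,
                w=measured.w - F0 * _unit_profile(measured.z, geom),
                sigma=measured.sigma)
    else:
        corrected = measured
    return _fit_single_force(corrected, geom)


def shear_strain(delta_x: float, L: float) -> float:
    """Pillar shear strain, tip displacement over pillar length (``Δx/L``)."""
    if L <= 0:
        raise ValidationError(f"L must be > 0, got {L}")
    return delta_x / L
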