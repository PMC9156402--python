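"""Fluorescence standard-curve calibration and myofilament counting.

A dilution series of labelled myosin monomer (known concentrations, measured
mean fluorescence) defines a linear standard curve ``I = slope·C +
intercept``.  A mean intensity measured in the sample is inverted through
the curve to the labelled-monomer concentration, scaled by the labelling
ratio to the total monomer concentration, converted to a molecule count in
the interrogated volume, and finally divided by the average number of
monomers per myofilament (monomer line density × filament length) to give a
myofilament count:

    C_label  = (I - intercept) / slope                       [µM]
    C_total  = C_label / labelling_ratio                     [µM]
    monomers = C_total · N_A · V                             [molecules]
    filaments = monomers / (monomer_density · filament_length)

Uncertainty in the measured intensity and in the fitted curve is propagated
to the counts by a first-order (delta-method) expansion, including the
slope–intercept covariance of the ordinary-least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError

__all__ = [
    "CalibrationSeries",
    "StandardCurve",
    "QuantConstants",
    "QuantResult",
    "fit_standard_curve",
    "count_myofilaments",
]

AVOGADRO = 6.02214076e23
#: molecules per µm³ at 1 µM: 1e-6 mol/L × N_A × 1e-15 L/µm³
MOLECULES_PER_UM3_PER_UM = AVOGADRO * 1e-21


@dataclass(frozen=True)
class CalibrationSeries:
    """Serial-dilution calibration data.

    ``concentration`` in µM labelled monomer, ``mean_intensity`` in camera
    arbitrary units, ``n_fields`` imaged fields per level.
    """

    concentration: np.ndarray
    mean_intensity: np.ndarray
    n_fields: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration, dtype=float)
        i = np.asarray(self.mean_intensity, dtype=float)
        object.__setattr__(self, "concentration", c)
        object.__setattr__(self, "mean_intensity", i)
        if c.shape != i.shape or c.ndim != 1:
            raise ValidationError(
                "concentration and mean_intensity must be 1D and equal length")
        if np.any(c < 0) or np.any(i < 0):
            raise ValidationError("concentrations and intensities must be >= 0")
        if len(np.unique(c)) < 3:
            raise ValidationError("need at least 3 distinct concentration levels")
        if self.n_fields is not None:
            n = np.asarray(self.n_fields, dtype=int)
            object.__setattr__(self, "n_fields", n)
            if n.shape != c.shape:
                raise ValidationError("n_fields must match the series length")

    def __len__(self) -> int:
        return len(self.concentration)


@dataclass(frozen=True)
class StandardCurve:
    """OLS line ``intensity = slope·C + intercept`` with standard errors."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    cov_slope_intercept: float
    dof: int


@dataclass(frozen=True)
class QuantConstants:
    """Constants converting a local labelled-myosin signal to filament counts.

    Defaults: 10% labelling ratio; interrogated volumes 1,055 µm³ (inner
    region) and 1,225 µm³ (ring region); 560 monomers per µm of myofilament;
    0.56 µm average myofilament length.
    """

    labelling_ratio: float = 0.10
    volume_inner: float = 1055.0
    volume_ring: float = 1225.0
    monomer_density: float = 560.0
    filament_length: float = 0.56

    def __post_init__(self) -> None:
        if not (0 < self.labelling_ratio <= 1):
            raise ValidationError(
                f"labelling_ratio must be in (0, 1], got {self.labelling_ratio}")
        for name in ("volume_inner", "volume_ring", "monomer_density",
                     "filament_length"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    @property
    def monomers_per_filament(self) -> float:
        return self.monomer_density * self.filament_length

    @property
    def volume_total(self) -> float:
        return self.volume_inner + self.volume_ring


@dataclass(frozen=True)
class QuantResult:
    """Myofilament count estimate with delta-method uncertainty."""

    local_concentration_label: float
    local_concentration_total: float
    monomer_count: float
    filament_count: float
    filament_count_inner: float
    filament_count_ring: float
    filament_count_se: float
    curve: StandardCurve


def fit_standard_curve(series: CalibrationSeries) -> StandardCurve:
    """Ordinary least-squares line through the calibration series.

    Raises
    ------
    ValidationError
        If the design is rank deficient (fewer than 3 distinct levels is
        rejected already at series construction).
    """
    c = series.concentration
    i = series.mean_intensity
    n = len(c)
    cbar = c.mean()
    sxx = np.sum((c - cbar) ** 2)
    if sxx == 0:
        raise ValidationError("rank-deficient calibration: one concentration level")
    slope = float(np.sum((c - cbar) * (i - i.mean())) / sxx)
    intercept = float(i.mean() - slope * cbar)
    resid = i - (slope * c + intercept)
    dof = n - 2
    s2 = float(np.sum(resid ** 2) / dof) if dof > 0 else 0.0
    var_slope = s2 / sxx
    var_intercept = s2 * (1.0 / n + cbar ** 2 / sxx)
    cov = -s2 * cbar / sxx
    return StandardCurve(slope=slope, intercept=intercept,
                         se_slope=float(np.sqrt(var_slope)),
                         se_intercept=float(np.sqrt(var_intercept)),
                         cov_slope_intercept=float(cov), dof=dof)


def count_myofilaments(measured_intensity: float,
                       curve: StandardCurve,
                       constants: QuantConstants = QuantConstants(),
                       intensity_sigma: float = 0.0) -> QuantResult:
    """Convert a measured mean intensity to a myofilament count.

    Parameters
    ----------
    measured_intensity : float
        Mean fluorescence in the interrogated region (same units and
        settings as the calibration series).
    intensity_sigma : float
        Measurement standard deviation of the intensity, propagated to the
        count together with the curve's parameter uncertainty.

    Raises
    ------
    ValidationError
        If the curve slope is not positive, or the intensity falls below the
        curve intercept (negative inferred concentration).
    """
    if curve.slope <= 0:
        raise ValidationError(f"curve slope must be > 0, got {curve.slope}")
    if measured_intensity < curve.intercept:
        raise ValidationError(
            f"intensity {measured_intensity} below curve intercept "
            f"{curve.intercept}: negative inferred concentration")
    c_label = (measured_intensity - curve.intercept) / curve.slope
    c_total = c_label / constants.labelling_ratio

    def filaments_in(volume: float) -> float:
        monomers = c_total * MOLECULES_PER_UM3_PER_UM * volume
        return monomers / constants.monomers_per_filament

    monomers_total = c_total * MOLECULES_PER_UM3_PER_UM * constants.volume_total
    filaments = monomers_total / constants.monomers_per_filament

    # delta method on C_label = (I - b)/m with dC/dI = 1/m, dC/db = -1/m,
    # dC/dm = -C/m; includes the OLS slope-intercept covariance
    m, b = curve.slope, curve.intercept
    var_c = ((intensity_sigma ** 2 + curve.se_intercept ** 2) / m ** 2
             + (c_label ** 2) * curve.se_slope ** 2 / m ** 2
             + 2.0 * c_label * curve.cov_slope_intercept / m ** 2)
    var_c = max(var_c, 0.0)
    scale = (MOLECULES_PER_UM3_PER_UM * constants.volume_total
             / (constants.labelling_ratio * constants.monomers_per_filament))
    filament_se = float(np.sqrt(var_c) * scale)

    return QuantResult(
        local_concentration_label=float(c_label),
        local_concentration_total=float(c_total),
        monomer_count=float(monomers_total),
        filament_count=float(filaments),
        filament_count_inner=float(filaments_in(constants.volume_inner)),
        filament_count_ring=float(filaments_in(constants.volume_ring)),
        filament_count_se=filament_se,
        curve=curve)
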