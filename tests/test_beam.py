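"""Euler-beam mechanics: closed forms, profile shape, force inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexforge import (DeflectionProfile, InsufficientDataError,
                         PillarGeometry, ValidationError, fit_force,
                         pillar_stiffness, predict_profile, second_moment,
                         shear_strain)


# --------------------------------------------------------------- geometry

def test_geometry_validation():
    with pytest.raises(ValidationError):
        PillarGeometry(L=15.0, d=20.0, E_kPa=57.0)  # d >= L
    with pytest.raises(ValidationError):
        PillarGeometry(L=15.0, d=2.0, E_kPa=-1.0)
    with pytest.raises(ValidationError):
        PillarGeometry(L=15.0, d=2.0, E_kPa=57.0, foot_cutoff=16.0)
    with pytest.raises(ValidationError):
        PillarGeometry(L=15.0, d=2.0, E_kPa=57.0, attach_height=20.0)


@pytest.mark.parametrize("d,expected", [
    (2.0, np.pi / 4.0),       # π d⁴/64 at d = 2
    (1.5, 0.24850),           # independently evaluated
])
def test_second_moment_values(d, expected):
    g = PillarGeometry(L=15.0, d=d, E_kPa=57.0)
    assert second_moment(g) == pytest.approx(expected, rel=1e-4)


def test_second_moment_quartic_scaling():
    g1 = PillarGeometry(L=15.0, d=1.0, E_kPa=57.0)
    g2 = PillarGeometry(L=15.0, d=2.0, E_kPa=57.0)
    assert second_moment(g2) / second_moment(g1) == pytest.approx(16.0)


def test_pillar_stiffness_reference_value(geom):
    # 3 E I / L^3 with E = 57 kPa, d = 2 µm, L = 15 µm; evaluated by hand
    assert pillar_stiffness(geom) == pytest.approx(39.7935, rel=1e-4)


def test_pillar_stiffness_scalings(geom):
    halved = PillarGeometry(L=30.0, d=2.0, E_kPa=57.0)
    assert pillar_stiffness(geom) / pillar_stiffness(halved) == \
        pytest.approx(8.0)
    soft = PillarGeometry(L=15.0, d=2.0, E_kPa=10.0)
    stiff = PillarGeometry(L=15.0, d=2.0, E_kPa=250.0)
    assert pillar_stiffness(stiff) / pillar_stiffness(soft) == \
        pytest.approx(25.0)


# ---------------------------------------------------------------- profiles

def test_zero_force_zero_profile(geom):
    prof = predict_profile(geom, 0.0)
    assert np.allclose(prof.w, 0.0)


def test_cubic_shape_ratio(geom):
    # w(L/2)/w(L) = 5/16 for tip loading, independent of F and geometry
    prof = predict_profile(geom, 77.0, z=np.array([0.0, geom.L / 2, geom.L]))
    assert prof.w[1] / prof.w[2] == pytest.approx(5.0 / 16.0, rel=1e-12)


def test_tip_deflection_closed_form(geom):
    # w(L) = F L³ / (3 E I) = 3.1663 µm at F = 126 pN (evaluated by hand)
    prof = predict_profile(geom, 126.0)
    assert prof.w[-1] == pytest.approx(3.1663, rel=1e-4)


def test_tip_deflection_equals_force_over_stiffness(geom):
    F = 200.0
    prof = predict_profile(geom, F)
    assert prof.w[-1] == pytest.approx(F / pillar_stiffness(geom), rel=1e-12)


def test_profile_convex_increasing(geom):
    prof = predict_profile(geom, 100.0, z=np.linspace(0, geom.L, 400))
    assert np.all(np.diff(prof.w) >= 0)
    assert np.all(np.diff(prof.w, 2) >= -1e-12)


def test_attach_height_profile_is_linear_above_load(geom):
    g = PillarGeometry(L=15.0, d=2.0, E_kPa=57.0, attach_height=10.0)
    z = np.linspace(10.0, 15.0, 20)
    prof = predict_profile(g, 50.0, z=z)
    # above the load point the beam is straight: second differences vanish
    assert np.allclose(np.diff(prof.w, 2), 0.0, atol=1e-12)


def test_profile_validation():
    with pytest.raises(ValidationError):
        DeflectionProfile(z=np.array([0.0, 1.0, 1.0]), w=np.zeros(3))
    with pytest.raises(ValidationError):
        DeflectionProfile(z=np.array([-1.0, 1.0]), w=np.zeros(2))
    with pytest.raises(ValidationError):
        DeflectionProfile(z=np.array([0.0, 1.0]), w=np.zeros(2),
                          sigma=np.array([0.1, 0.0]))


# -------------------------------------------------------------- force fit

@settings(max_examples=50, deadline=None, derandomize=True)
@given(F=st.floats(-500.0, 500.0),
       d=st.floats(1.0, 4.0), L=st.floats(8.0, 30.0),
       E=st.floats(10.0, 250.0))
def test_fit_force_round_trip(F, d, L, E):
    if d >= L:
        return
    g = PillarGeometry(L=L, d=d, E_kPa=E)
    prof = predict_profile(g, F, z=np.linspace(0, L, 30))
    F_hat, rms = fit_force(prof, geom=g)
    assert F_hat == pytest.approx(F, rel=1e-9, abs=1e-9)
    assert rms < 1e-9


def test_foot_samples_ignored(geom):
    z = np.linspace(0, geom.L, 31)
    prof = predict_profile(geom, 100.0, z=z)
    corrupted = DeflectionProfile(
        z=z, w=np.where(z < 2.0, 17.0, prof.w))  # garbage below the foot
    F_ref, _ = fit_force(prof, geom=geom)
    F_cor, _ = fit_force(corrupted, geom=geom)
    assert F_cor == pytest.approx(F_ref, rel=1e-12)


def test_initial_profile_correction(geom):
    """A pre-bent pillar: fitting subtracts the fitted initial shape."""
    z = np.linspace(0, geom.L, 31)
    F0, F = 30.0, 100.0
    initial = predict_profile(geom, F0, z=z)
    measured = predict_profile(geom, F0 + F, z=z)
    F_hat, _ = fit_force(measured, initial=initial, geom=geom)
    assert F_hat == pytest.approx(F, rel=1e-9)
    F_raw, _ = fit_force(measured, initial=initial, geom=geom,
                         subtract_raw=True)
    assert F_raw == pytest.approx(F, rel=1e-9)


def test_fit_force_unbiased_and_efficient(geom, rng):
    """Monte Carlo: mean within 1% of truth, SD within 20% of closed form."""
    F_true = 126.0
    z = np.linspace(0, geom.L, 30)
    clean = predict_profile(geom, F_true, z=z)
    sigma = 0.1
    estimates = []
    for _ in range(1000):
        noisy = DeflectionProfile(z=z, w=clean.w + rng.normal(0, sigma, 30))
        F_hat, _ = fit_force(noisy, geom=geom)
        estimates.append(F_hat)
    estimates = np.asarray(estimates)
    # closed-form linear-regression SD: sigma / sqrt(sum s(z)^2) over kept z
    kept = z >= geom.foot_cutoff
    s = clean.w[kept] / F_true
    sd_theory = sigma / np.sqrt(np.sum(s ** 2))
    assert abs(estimates.mean() - F_true) < 0.01 * F_true
    assert abs(estimates.std() - sd_theory) < 0.2 * sd_theory


def test_weighted_fit_uses_uncertainties(geom):
    z = np.linspace(0, geom.L, 31)
    clean = predict_profile(geom, 100.0, z=z)
    # one wild outlier with huge stated uncertainty barely moves the fit
    w = clean.w.copy()
    w[-1] += 5.0
    sigma = np.full(31, 0.01)
    sigma[-1] = 100.0
    F_hat, _ = fit_force(DeflectionProfile(z=z, w=w, sigma=sigma), geom=geom)
    assert F_hat == pytest.approx(100.0, rel=1e-3)


def test_all_samples_below_cutoff_errors(geom):
    prof = DeflectionProfile(z=np.array([0.5, 1.0, 1.5]), w=np.zeros(3))
    with pytest.raises(InsufficientDataError):
        fit_force(prof, geom=geom)


# ------------------------------------------------------------ shear strain

@pytest.mark.parametrize("dx,L,expected", [
    (0.0, 15.0, 0.0),
    (4.5, 15.0, 0.3),   # the maximal strain scale of the assay
    (15.0, 15.0, 1.0),
])
def test_shear_strain(dx, L, expected):
    assert shear_strain(dx, L) == pytest.approx(expected)


def test_shear_strain_requires_positive_length():
    with pytest.raises(ValidationError):
        shear_strain(1.0, 0.0)
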