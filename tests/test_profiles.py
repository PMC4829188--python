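"""Analytic pulse shapes and the attractant convolution against quadrature."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import chemopulse as cp
from chemopulse.dispersion import single_species_speed, two_species_speed
from chemopulse.profiles import (
    build_wave_profile,
    chemoattractant_profile,
    decay_rates,
    peak_amplitude,
    s_prime_zero_residual,
)

from conftest import quad_attractant, quad_attractant_slope_at_peak, quad_mass


def test_decay_rates_signs_and_difference_identity(params):
    for sp in params.species:
        sigma = single_species_speed(sp, params.fields)
        lm, lp = decay_rates(sigma, sp)
        assert lm > 0.0 > lp
        assert lm - lp == pytest.approx(2.0 * sp.chi_S / sp.D, rel=1e-12)


def test_decay_rates_symmetric_at_chi_N(params):
    sp = params.species[0]
    lm, lp = decay_rates(sp.chi_N, sp)
    assert lm == pytest.approx(sp.chi_S / sp.D, rel=1e-12)
    assert lp == pytest.approx(-sp.chi_S / sp.D, rel=1e-12)


def test_decay_rates_reject_speed_outside_interval(params):
    sp = params.species[0]
    with pytest.raises(ValueError, match="no traveling pulse"):
        decay_rates(sp.chi_N + 2.0 * sp.chi_S, sp)


def test_peak_amplitude_mass_round_trip(params):
    """Quadrature of the assembled pulse returns the prescribed mass."""
    profile = build_wave_profile(params, 0.1)
    for i, mass in ((0, 0.9 * params.mix.total), (1, 0.1 * params.mix.total)):
        assert quad_mass(profile, i) == pytest.approx(mass, rel=1e-8)
        assert profile.mass(i) == pytest.approx(mass, rel=1e-12)


def test_peak_amplitude_linearity_and_validation():
    assert peak_amplitude(2.0, 50.0, -20.0) == 2.0 * peak_amplitude(1.0, 50.0, -20.0)
    with pytest.raises(ValueError):
        peak_amplitude(0.0, 50.0, -20.0)


def test_pulse_monotone_flanks(params):
    profile = build_wave_profile(params, 0.1)
    z = np.linspace(-0.1, 0.1, 2001)
    for i in range(2):
        rho = profile.rho(z, i)
        left = rho[z < 0]
        right = rho[z > 0]
        assert np.all(np.diff(left) > 0)
        assert np.all(np.diff(right) < 0)


def test_kernel_positive_continuous_and_even_at_zero_speed(params):
    k_moving = cp.Kernel(sigma=2.5e-4, D_S=params.fields.D_S, alpha=params.fields.alpha)
    z = np.linspace(-0.05, 0.05, 101)
    assert np.all(k_moving(z) > 0.0)
    assert k_moving(-1e-12) == pytest.approx(float(k_moving(1e-12)), rel=1e-6)
    k_still = cp.Kernel(sigma=0.0, D_S=params.fields.D_S, alpha=params.fields.alpha)
    assert np.allclose(k_still(z), k_still(-z))


def test_attractant_closed_form_matches_quadrature(params):
    """Analytic piecewise-exponential S equals the adaptive convolution."""
    profile = build_wave_profile(params, 0.1)
    S = chemoattractant_profile(profile, params.fields)
    z_points = np.concatenate(
        [np.linspace(-0.15, 0.15, 48), [-1e-6, 1e-6]]
    )
    for z in z_points:
        assert float(S(z)) == pytest.approx(
            quad_attractant(profile, params.fields, float(z)), rel=1e-8
        )


def test_attractant_is_a_pulse(params):
    """S decays at infinity with a unique maximum at the density peak."""
    profile = build_wave_profile(params, 0.1)
    S = chemoattractant_profile(profile, params.fields)
    z = np.linspace(-0.5, 0.5, 4001)
    vals = S(z)
    assert np.all(vals > 0.0)
    assert np.all(np.diff(vals[z < 0]) > 0)
    assert np.all(np.diff(vals[z > 0]) < 0)
    assert vals[0] < 1e-3 * vals.max() and vals[-1] < 1e-3 * vals.max()


def test_attractant_even_for_symmetric_still_pulse(params):
    """With no nutrient bias the pulse is still and S is an even function."""
    sp = dataclasses.replace(params.species[0], chi_N=0.0)
    lm, lp = decay_rates(0.0, sp)
    profile = cp.WaveProfile(
        sigma=0.0, lam_minus=(lm, lm), lam_plus=(lp, lp), rho_max=(1.0, 0.0)
    )
    S = chemoattractant_profile(profile, params.fields)
    z = np.linspace(0.001, 0.2, 200)
    assert np.allclose(S(z), S(-z), rtol=1e-12)


def test_attractant_slope_zero_at_peak_only_at_dispersion_root(params):
    phi = 0.15
    sigma = two_species_speed(params, phi)
    profile = build_wave_profile(params, phi)
    S = chemoattractant_profile(profile, params.fields)
    scale = abs(float(S(0.0))) * profile.lam_minus[0]
    assert abs(float(S.derivative(0.0))) < 1e-10 * scale
    # off the root the slope is nonzero
    off = build_wave_profile(params, phi, sigma=sigma * 1.01)
    S_off = chemoattractant_profile(off, params.fields)
    assert abs(float(S_off.derivative(0.0))) > 1e-6 * scale


def test_closed_form_slope_matches_quadrature(params):
    profile = build_wave_profile(params, 0.3)
    S = chemoattractant_profile(profile, params.fields)
    assert float(S.derivative(0.0)) == pytest.approx(
        quad_attractant_slope_at_peak(profile, params.fields), abs=1e-8 * float(S(0.0))
    )


def test_s_prime_residual_vanishes_at_root_and_flips_sign(params):
    phi = 0.2
    sigma = two_species_speed(params, phi)
    scale = abs(s_prime_zero_residual(sigma * 1.02, params, phi))
    assert abs(s_prime_zero_residual(sigma, params, phi)) < 1e-10 * scale
    below = s_prime_zero_residual(sigma * 0.995, params, phi)
    above = s_prime_zero_residual(sigma * 1.005, params, phi)
    assert below * above < 0.0


def test_s_prime_residual_single_species_reduction(params):
    s1 = single_species_speed(params.species[0], params.fields)
    assert s_prime_zero_residual(s1, params, 0.0) == pytest.approx(0.0, abs=1e-12)


def test_resonance_is_regularized_with_warning(params):
    """A flank rate exactly matching a kernel rate triggers the perturbation."""
    fl = params.fields
    chi_S = np.sqrt(fl.alpha / fl.D_S)  # makes lam^- = mu^- at sigma = 0, D = 1
    sp = cp.SpeciesParams(D=1.0, chi_S=chi_S, chi_N=0.0)
    lm, lp = decay_rates(0.0, sp)
    profile = cp.WaveProfile(
        sigma=0.0, lam_minus=(lm, lm), lam_plus=(lp, lp), rho_max=(1.0, 0.0)
    )
    with pytest.warns(UserWarning, match="resonance"):
        S = chemoattractant_profile(profile, fl)
    assert np.isfinite(float(S(0.01)))
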