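"""Scalar building blocks: monotonicity, signs, and algebraic identities."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chemopulse as cp
from chemopulse.core import big_G, big_H, g, h, h_factored
from chemopulse.dispersion import single_species_speed


def species_strategy():
    return st.builds(
        cp.SpeciesParams,
        D=st.floats(1e-7, 1e-5),
        chi_S=st.floats(1e-5, 5e-4),
        chi_N=st.floats(1e-5, 1e-3),
        gamma=st.just(1.0),
    )


def fields_strategy():
    return st.builds(
        cp.FieldParams,
        D_S=st.floats(1e-6, 1e-4),
        D_N=st.just(8e-6),
        alpha=st.floats(1e-3, 1.0),
    )


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    species_strategy(),
    fields_strategy(),
    st.floats(-1e-3, 1e-3),
    st.floats(1e-9, 1e-3),
)
def test_g_strictly_increasing(sp, fl, sigma, gap):
    """g grows with trial speed for any admissible parameter set."""
    assert g(sigma, sp, fl) < g(sigma + gap, sp, fl)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(species_strategy(), fields_strategy())
def test_g_brackets_its_root(sp, fl):
    """g is negative at the left end of I and positive at the right end."""
    assert g(sp.chi_N - sp.chi_S, sp, fl) < 0.0
    assert g(sp.chi_N + sp.chi_S, sp, fl) > 0.0


def test_g_vanishes_at_chi_N_without_attractant_response(params):
    sp = dataclasses.replace(params.species[0], chi_S=0.0)
    assert g(sp.chi_N, sp, params.fields) == pytest.approx(0.0, abs=1e-18)


def test_g_direct_evaluation_at_chi_N(params):
    """At sigma = chi^N only the attractant term survives, and it is positive."""
    sp, fl = params.species[0], params.fields
    sigma = sp.chi_N
    expected = sp.chi_S * sigma / np.sqrt(sigma**2 + 4 * fl.alpha * fl.D_S)
    assert g(sigma, sp, fl) == pytest.approx(expected, rel=1e-14)
    assert expected > 0.0


def test_h_negative_inside_admissible_interval(params):
    for sp in params.species:
        iv = sp.interval().interior(1e-6)
        for sigma in np.linspace(iv.lo, iv.hi, 200):
            assert h(sigma, sp, params.fields) < 0.0


def test_h_matches_factored_form(params):
    """The polynomial form equals the two-factor product times 4 D_S / D."""
    rng = np.random.default_rng(0)
    for sp in params.species:
        iv = sp.interval()
        sigmas = iv.lo + iv.width * rng.random(100)
        for sigma in sigmas:
            lhs = h_factored(sigma, sp, params.fields)
            rhs = 4.0 * params.fields.D_S / sp.D * h(sigma, sp, params.fields)
            assert lhs == pytest.approx(rhs, rel=1e-10)


def test_h_all_terms_nonpositive_at_zero_speed_no_nutrient_bias(params):
    sp = dataclasses.replace(params.species[0], chi_N=0.0)
    fl = params.fields
    expected = (
        -sp.chi_S * 2.0 * np.sqrt(fl.alpha * fl.D_S)
        - (fl.D_S / sp.D) * sp.chi_S**2
        - fl.alpha * sp.D
    )
    assert h(0.0, sp, fl) == pytest.approx(expected, rel=1e-12)
    assert expected < 0.0


def test_H_positive_on_interior(params):
    overlap = params.overlap().interior(1e-6)
    for sigma in np.linspace(overlap.lo, overlap.hi, 200):
        assert big_H(sigma, params) > 0.0


def test_H_is_unity_for_identical_species(params):
    sp = params.species[0]
    twin = dataclasses.replace(
        params, species=(sp, dataclasses.replace(sp, D=sp.D * (1 + 1e-12)))
    )
    sigma = sp.chi_N  # interior of the (common) interval
    assert big_H(sigma, twin) == pytest.approx(1.0, rel=1e-6)


def test_H_raises_at_interval_endpoint(params):
    with pytest.raises(ValueError, match="singular"):
        big_H(params.species[0].chi_N + params.species[0].chi_S, params)


def test_G_vanishes_at_sigma1_and_is_positive_inside(params):
    s1 = single_species_speed(params.species[0], params.fields)
    assert big_G(s1, params) == pytest.approx(0.0, abs=1e-12)
    hi = params.species[0].chi_N + params.species[0].chi_S
    for sigma in np.linspace(s1, hi, 100)[1:-1]:
        assert big_G(sigma, params) > 0.0
    # continuous and finite up to the right endpoint
    assert np.isfinite(big_G(hi - 1e-12 * hi, params))


def test_G_substitute_back_identity(params):
    """Where G(sigma)=r, the mixed relation with phi/(1-phi)=r has residual 0."""
    s1 = single_species_speed(params.species[0], params.fields)
    hi = params.species[0].chi_N + params.species[0].chi_S
    for sigma in np.linspace(s1, hi, 17)[1:-1]:
        r = big_G(sigma, params)
        resid = g(sigma, params.species[0], params.fields) + r * big_H(
            sigma, params
        ) * g(sigma, params.species[1], params.fields)
        scale = max(
            abs(g(sigma, params.species[0], params.fields)),
            abs(g(sigma, params.species[1], params.fields)),
        )
        assert abs(resid) < 1e-10 * scale


def test_speed_scales_exactly_with_length_unit(params):
    """Re-expressing all lengths in um multiplies the wave speed by 1e4."""
    factor = 1e4  # cm -> um
    sp = params.species[0]
    sp_um = dataclasses.replace(
        sp, D=sp.D * factor**2, chi_S=sp.chi_S * factor, chi_N=sp.chi_N * factor
    )
    fl = params.fields
    fl_um = dataclasses.replace(
        fl, D_S=fl.D_S * factor**2, D_N=fl.D_N * factor**2
    )
    s_cm = single_species_speed(sp, fl)
    s_um = single_species_speed(sp_um, fl_um)
    assert s_um == pytest.approx(s_cm * factor, rel=1e-12)


def test_species_reindexed_when_misordered(params):
    """Constructing with fast species first silently restores slow-first order."""
    swapped = cp.ModelParams(
        species=(params.species[1], params.species[0]),
        fields=params.fields,
        mix=cp.PopulationMix(M1=params.mix.M2, M2=params.mix.M1),
    )
    assert swapped.species[0] == params.species[0]
    assert swapped.mix.M1 == params.mix.M1


def test_param_file_round_trip(tmp_path, params):
    for name in ("p.yaml", "p.json"):
        path = tmp_path / name
        cp.save_params(params, path)
        again = cp.load_params(path)
        assert again == params


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        cp.SpeciesParams(D=-1e-6, chi_S=1e-4, chi_N=1e-4)
    with pytest.raises(ValueError):
        cp.FieldParams(D_S=1e-6, D_N=1e-6, alpha=0.0)
    with pytest.raises(ValueError):
        cp.PopulationMix(M1=0.0, M2=0.0)
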