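"""Venation scaling: shape-to-network mapping and xylem resistance algebra."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafopt import venation
from leafopt.params import LeafTraits, default_params


def with_traits(**kw):
    return dataclasses.replace(default_params().traits, **kw)


# ---------------------------------------------------------------------------
# shape -> gamma, l0, T
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("k_SP,expected", [(0.28, 0.14), (0.35, 0.175)])
def test_gamma_is_half_shape_ratio(k_SP, expected):
    assert venation.gamma_from_shape(k_SP) == pytest.approx(expected)


def test_gamma_rejects_degenerate_shape():
    with pytest.raises(ValueError):
        venation.gamma_from_shape(2.0)
    with pytest.raises(ValueError):
        venation.gamma_from_shape(0.0)


def test_major_vein_length_is_leaf_length():
    # mean leaf area 16 cm^2, shape 0.25 -> an 8 cm long leaf
    assert venation.major_vein_length(16e-4, 0.25) == pytest.approx(0.08)
    assert venation.major_vein_length(0.3, 0.3) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        venation.major_vein_length(0.0, 0.25)


def test_vein_order_two_forms_agree():
    """The expanded log formula equals log base gamma of l_T/l0 to 1e-12."""
    for LA, k_SP, l_T in [(16e-4, 0.5, 150e-6), (1e-3, 0.28, 150e-6),
                          (5e-2, 0.35, 2e-4)]:
        expanded = (-2 * math.log(l_T) - math.log(k_SP) + math.log(LA)) / \
            (2 * math.log(2) - 2 * math.log(k_SP))
        assert venation.vein_order(LA, k_SP, l_T) == \
            pytest.approx(expanded, rel=1e-12)


def test_vein_order_reference_value():
    # frozen from the closed form: ln(l_T/sqrt(LA/k_SP)) / ln(k_SP/2)
    T = venation.vein_order(16e-4, 0.5, 150e-6)
    assert T == pytest.approx(4.2794468, rel=1e-6)


def test_vein_order_increases_with_shape_ratio():
    T_narrow = venation.vein_order(16e-4, 0.28, 150e-6)
    T_broad = venation.vein_order(16e-4, 0.35, 150e-6)
    assert T_broad > T_narrow


def test_vein_order_degenerate_leaf():
    # terminal vein as long as the major vein: T = 0 at equality, error above
    k_SP, LA = 0.5, 16e-4
    l0 = venation.major_vein_length(LA, k_SP)
    with pytest.raises(ValueError):
        venation.vein_order(LA, k_SP, l0 * 1.01)
    assert venation.vein_order(LA, k_SP, l0 * (1 - 1e-12)) == \
        pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# conduit scaling
# ---------------------------------------------------------------------------

def test_conduit_scaling_powers():
    # two orders of beta=0.5 taper: conduits 4x wider upstream, 16x fewer
    m, M0, r0 = venation.conduit_scaling(2.0, with_traits(beta=0.5, M_T=1.0))
    assert (m, M0, r0) == (4.0, pytest.approx(1 / 16), pytest.approx(4 * 3e-6))


def test_no_taper_limit():
    m, M0, r0 = venation.conduit_scaling(
        5.0, with_traits(beta=1 - 1e-12, M_T=2.0))
    assert m == pytest.approx(1.0)
    assert M0 == pytest.approx(2.0)
    assert r0 == pytest.approx(3e-6)


@settings(max_examples=200, deadline=None)
@given(beta=st.floats(0.05, 0.95), T=st.floats(0.0, 12.0))
def test_cross_section_conservation(beta, T):
    """M0*r0^2 = M_T*r_T^2 exactly, for any taper and depth."""
    traits = with_traits(beta=beta)
    _, M0, r0 = venation.conduit_scaling(T, traits)
    assert M0 * r0**2 == pytest.approx(traits.M_T * traits.r_T**2,
                                       rel=1e-12)


def test_terminal_vein_spacing():
    assert venation.terminal_vein_spacing(300e-6, 1.0) == \
        pytest.approx(150e-6)
    assert venation.terminal_vein_spacing(250e-6, 1.0) == \
        pytest.approx(125e-6)
    with pytest.raises(ValueError):
        venation.terminal_vein_spacing(300e-6, 0.5)


# ---------------------------------------------------------------------------
# xylem resistance: closed form vs per-order sum oracle
# ---------------------------------------------------------------------------

def _closed_at_integer_T(T_int, traits, env):
    """Evaluate the closed form at an LA chosen so vein_order is exactly T."""
    g = venation.gamma_from_shape(traits.k_SP)
    l0 = traits.l_T / g**T_int
    LA = traits.k_SP * l0**2
    assert venation.vein_order(LA, traits.k_SP, traits.l_T) == \
        pytest.approx(T_int, rel=1e-12, abs=1e-12)
    return venation.xylem_resistance_closed(LA, traits, env)


def test_single_segment_path(env):
    traits = with_traits()
    base = 8 * env.mu / env.rho_w * traits.l_T / traits.r_T**2
    assert _closed_at_integer_T(0, traits, env) == pytest.approx(base)
    assert venation.xylem_resistance_sum(0, traits, env) == \
        pytest.approx(base)


def test_two_term_sum(env):
    traits = with_traits(beta=0.3, k_SP=0.28)
    q = venation.resistance_series_ratio(traits)
    base = 8 * env.mu / env.rho_w * traits.l_T / traits.r_T**2
    assert venation.xylem_resistance_sum(1, traits, env) == \
        pytest.approx(base * (1 + q), rel=1e-12)


@settings(max_examples=100, deadline=None)
@given(beta=st.floats(0.1, 0.9), k_SP=st.floats(0.1, 0.5),
       T_int=st.integers(0, 12))
def test_closed_form_equals_explicit_sum(beta, k_SP, T_int):
    env = default_params().env
    traits = with_traits(beta=beta, k_SP=k_SP)
    closed = _closed_at_integer_T(T_int, traits, env)
    explicit = venation.xylem_resistance_sum(T_int, traits, env)
    assert closed == pytest.approx(explicit, rel=1e-10)


def test_sum_rejects_non_integer_order(env):
    with pytest.raises(ValueError):
        venation.xylem_resistance_sum(2.5, with_traits(), env)


def test_series_limit_at_unit_ratio(env):
    """As the per-order ratio q -> 1, the path reduces to (T+1) equal
    segments; checked from both sides at |q-1| = 1e-6."""
    base_traits = with_traits(k_SP=0.28)
    g = venation.gamma_from_shape(base_traits.k_SP)
    n = venation.vein_branching_ratio(base_traits.k_SP)
    base = 8 * env.mu / env.rho_w * base_traits.l_T / base_traits.r_T**2
    for eps in (1e-6, -1e-6):
        beta = math.sqrt((1 + eps) * g / n)
        traits = with_traits(k_SP=0.28, beta=beta)
        T_int = 5
        closed = _closed_at_integer_T(T_int, traits, env)
        assert closed == pytest.approx(base * (T_int + 1), rel=1e-4)


def test_resistance_monotone_in_area_and_shape(env):
    """r_Xtotal rises with leaf area and falls with W/L at fixed area."""
    las = np.geomspace(1e-4, 1e-2, 20)
    narrow = venation.xylem_resistance_closed(las, with_traits(k_SP=0.1), env)
    broad = venation.xylem_resistance_closed(las, with_traits(k_SP=0.5), env)
    assert np.all(np.diff(narrow) > 0)
    assert np.all(np.diff(broad) > 0)
    assert np.all(narrow > broad)


def test_resistance_finite_over_two_decades(env):
    las = np.geomspace(1e-4, 1e-2, 50)
    for k_SP in (0.1, 0.28, 0.5):
        r = venation.xylem_resistance_closed(las, with_traits(k_SP=k_SP), env)
        assert np.all(np.isfinite(r)) and np.all(r > 0)


def test_derivative_matches_finite_difference(env):
    traits = with_traits()
    for LA in (1e-4, 1.6e-3, 1e-2):
        h = LA * 1e-6
        fd = (venation.xylem_resistance_closed(LA + h, traits, env)
              - venation.xylem_resistance_closed(LA - h, traits, env)) / (2 * h)
        assert venation.xylem_resistance_dLA(LA, traits, env) == \
            pytest.approx(fd, rel=1e-6)


def test_summary_consistency(env):
    traits = with_traits()
    s = venation.summarize(16e-4, traits, env)
    assert s.gamma == pytest.approx(traits.k_SP / 2)
    assert s.n == pytest.approx(1 / s.gamma**2)
    assert s.M0 * s.r0**2 == pytest.approx(traits.M_T * traits.r_T**2)
    assert s.r_Xtotal == pytest.approx(
        venation.xylem_resistance_closed(16e-4, traits, env))
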