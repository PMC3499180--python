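"""Cell-level growth laws: stress modulation, maturation, growth tensors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from growthplate import kinetics
from growthplate.kinetics import (
    CellDistribution,
    ChondrocyteColumn,
    GrowthRateTensor,
    chondrocyte_height,
    d_hmax,
    distribution_tensor,
    growth_rate,
    growth_tensor,
    hypertrophy_strain_rate,
    max_hypertrophic_height,
    proliferation_strain_rate,
    steady_state_column,
    stress_difference,
    time_step,
)
from growthplate.parameters import TABULATED_LOAD_CASES, get_load_case

Y = np.array([0.0, 1.0])


# ---------------------------------------------------------------------------
# stress difference and terminal-height modulation
# ---------------------------------------------------------------------------

def test_stress_difference_is_plain_subtraction():
    assert stress_difference(-0.2, 0.0) == -0.2
    assert stress_difference(0.3, 0.3) == 0.0
    assert stress_difference(0.05, -0.05) == pytest.approx(0.10)


@pytest.mark.parametrize(
    "ds,expected",
    [(0.1, 0.035), (0.0, 0.0), (-0.1, 0.027), (-0.2, -0.020)],
)
def test_terminal_height_modulation_fraction(ds, expected):
    assert d_hmax(ds) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "ds,h_max",
    [(0.1, 36.22), (0.0, 35.00), (-0.1, 35.94), (-0.2, 34.30)],
)
def test_terminal_height_reproduces_tabulated_values(ds, h_max):
    assert max_hypertrophic_height(ds, 35.0) == pytest.approx(h_max, abs=0.01)


def test_terminal_height_rejects_nonpositive_baseline():
    with pytest.raises(ValueError):
        max_hypertrophic_height(0.0, 0.0)


# ---------------------------------------------------------------------------
# maturation ramp
# ---------------------------------------------------------------------------

def test_maturation_ramp_endpoints_and_midpoint():
    assert chondrocyte_height(12.0, 36.0, 0.0, 1.0) == 12.0
    assert chondrocyte_height(12.0, 36.0, 1.0, 1.0) == 36.0
    assert chondrocyte_height(12.0, 36.0, 0.5, 1.0) == pytest.approx(24.0)


@pytest.mark.parametrize("age", [-0.1, 1.1])
def test_maturation_age_outside_window_rejected(age):
    with pytest.raises(ValueError):
        chondrocyte_height(12.0, 36.0, age, 1.0)


@settings(deadline=None)
@given(
    h_p=st.floats(1.0, 30.0),
    dh=st.floats(0.1, 30.0),
    t_E=st.floats(0.1, 10.0),
    frac=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=8),
)
def test_maturation_ramp_monotone_and_bounded(h_p, dh, t_E, frac):
    h_max = h_p + dh
    ages = sorted(f * t_E for f in frac)
    heights = [chondrocyte_height(h_p, h_max, a, t_E) for a in ages]
    assert all(h_p <= h <= h_max + 1e-12 for h in heights)
    assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))


# ---------------------------------------------------------------------------
# growth rate and turnover interval
# ---------------------------------------------------------------------------

def test_growth_rate_is_product():
    assert growth_rate(1 / 0.161, 35.00) == pytest.approx(217.4, abs=0.05)
    assert growth_rate(0.0, 40.0) == 0.0
    assert growth_rate(1 / 0.158, 36.22) == pytest.approx(229.2, abs=0.05)


def test_time_step_examples_and_guard():
    assert time_step(36.22, 228.7) == pytest.approx(0.158, abs=5e-4)
    assert time_step(35.94, 183.4) == pytest.approx(0.196, abs=5e-4)
    assert time_step(17.0, 17.0) == 1.0
    with pytest.raises(ValueError):
        time_step(35.0, 0.0)


def test_time_step_reproduces_all_tabulated_intervals():
    for ds in TABULATED_LOAD_CASES:
        lc = get_load_case(ds)
        h_max = max_hypertrophic_height(ds, 35.0)
        assert time_step(h_max, lc.G_stokes) == pytest.approx(lc.delta_t, abs=0.001)


def test_growth_rate_monotone_in_stress_across_cases():
    """Compression retards growth, tension promotes it."""
    rates = [max_hypertrophic_height(ds) / get_load_case(ds).delta_t for ds in TABULATED_LOAD_CASES]
    assert rates == sorted(rates)  # TABULATED_LOAD_CASES is ascending in stress


# ---------------------------------------------------------------------------
# growth tensors
# ---------------------------------------------------------------------------

def test_proliferation_tensor_plugin_value():
    d = proliferation_strain_rate(6.211, 12.0, 264.0, Y)
    assert d.rate_nn == pytest.approx(0.2823, abs=2e-4)
    T = d.tensor
    assert T[1, 1] == pytest.approx(d.rate_nn)
    assert T[0, 0] == 0 and T[0, 1] == 0 and T[1, 0] == 0


def test_proliferation_tensor_zero_rate():
    assert proliferation_strain_rate(0.0, 12.0, 264.0, Y).rate_nn == 0.0


def test_hypertrophy_tensor_trivial_and_single_cell():
    col = ChondrocyteColumn(22, [(0.5, 12.0), (1.0, 12.0)])
    assert hypertrophy_strain_rate(col, 12.0, 162.0, Y).rate_nn == 0.0
    col = ChondrocyteColumn(22, [(0.5, 17.0)])
    assert hypertrophy_strain_rate(col, 12.0, 162.0, Y).rate_nn == pytest.approx(10.0 / 162.0)


def test_hypertrophy_zero_age_with_elongation_is_rejected():
    col = ChondrocyteColumn(22, [(0.0, 15.0)])
    with pytest.raises(ValueError):
        hypertrophy_strain_rate(col, 12.0, 162.0, Y)


def test_hypertrophy_steady_state_matches_explicit_sum():
    n_h, dt, h_p, h_max, l_h = 6, 0.161, 12.0, 35.0, 162.0
    col = steady_state_column(22, n_h, h_p, h_max, dt)
    t_E = n_h * dt
    explicit = sum((h - h_p) / a for a, h in col.hypertrophic_cells) / l_h
    closed = n_h * (h_max - h_p) / (t_E * l_h)
    assert hypertrophy_strain_rate(col, h_p, l_h, Y).rate_nn == pytest.approx(explicit)
    assert explicit == pytest.approx(closed, rel=1e-12)


def test_growth_tensor_addition_and_direction_guard():
    a = GrowthRateTensor(Y, 0.1)
    b = GrowthRateTensor(Y, 0.25)
    assert growth_tensor(a, b).rate_nn == pytest.approx(0.35)
    assert growth_tensor(a, GrowthRateTensor(Y, 0.0)).rate_nn == a.rate_nn
    with pytest.raises(ValueError):
        growth_tensor(a, GrowthRateTensor(np.array([1.0, 0.0]), 0.1))


@settings(deadline=None)
@given(
    dt=st.floats(0.05, 1.0),
    h_p=st.floats(5.0, 20.0),
    dh=st.floats(1.0, 30.0),
    l_p=st.floats(50.0, 500.0),
    l_h=st.floats(50.0, 500.0),
    n_h=st.integers(1, 12),
)
def test_master_steady_state_identity(dt, h_p, dh, l_p, l_h, n_h):
    """l_p * rate_prolif + l_h * rate_hyper = n_p * h_max in equilibrium."""
    h_max = h_p + dh
    n_p = 1.0 / dt
    col = steady_state_column(22, n_h, h_p, h_max, dt)
    d_p = proliferation_strain_rate(n_p, h_p, l_p, Y)
    d_h = hypertrophy_strain_rate(col, h_p, l_h, Y)
    total = l_p * d_p.rate_nn + l_h * d_h.rate_nn
    assert total == pytest.approx(n_p * h_max, rel=1e-10)


# ---------------------------------------------------------------------------
# distribution tensor
# ---------------------------------------------------------------------------

def test_distribution_tensor_isotropic_cases():
    np.testing.assert_allclose(
        distribution_tensor(CellDistribution(1.0, Y, concentration=3.0)), 3.0 * np.eye(2)
    )
    np.testing.assert_allclose(distribution_tensor(CellDistribution(1.0, Y)), np.eye(2))


def test_distribution_tensor_anisotropy_unsupported():
    with pytest.raises(NotImplementedError):
        distribution_tensor(CellDistribution(2.0, Y))


def test_cell_distribution_validates_inputs():
    with pytest.raises(ValueError):
        CellDistribution(0.0, Y)
    with pytest.raises(ValueError):
        CellDistribution(1.0, np.array([1.0, 1.0]))
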