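"""Constitutive relations: force-length, force-velocity, SEC, PEC, scalars."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hillcalf.muscle_model import (
    MuscleParameters,
    ParameterError,
    activation,
    cc_force,
    csa_and_stress,
    force_length,
    force_velocity,
    inverse_force_velocity,
    load_fixture,
    load_parameters,
    pec_force,
    save_parameters,
    sec_elongation,
    sec_force,
    sec_linear_stiffness,
    sec_strain_at_fim,
)

ALL = ["gas", "pla", "sol"]


# -- force-length -------------------------------------------------------------

@pytest.mark.parametrize("name", ALL)
def test_force_length_breakpoints(name):
    """f_l hits (0, f_c, 1, 1, 0) at the five breakpoints of every muscle."""
    p = load_fixture(name)
    vals = force_length(np.array([p.l1, p.l2, 1.0, p.l3, p.l4]), p)
    assert vals == pytest.approx([0.0, p.f_c, 1.0, 1.0, 0.0], abs=1e-12)


def test_force_length_examples():
    gas = load_fixture("gas")
    assert force_length(1.0, gas) == 1.0
    assert force_length(gas.l2, gas) == pytest.approx(0.85)
    # ascending segment 2 passes through (l2, f_c) and (1, 1)
    assert force_length(0.90, gas) == pytest.approx(0.85 + 0.15 * (0.90 - 0.82) / 0.18, rel=1e-12)
    assert force_length(0.0, gas) == 0.0
    assert force_length(3.0, gas) == 0.0


@pytest.mark.parametrize("name", ALL)
def test_force_length_continuous(name):
    p = load_fixture(name)
    x = np.linspace(0, p.l4 + 0.5, 20001)
    y = force_length(x, p)
    # piecewise linear with bounded slope => bounded successive differences
    max_slope = max(p.f_c / (p.l2 - p.l1), (1 - p.f_c) / (1 - p.l2), 1 / (p.l4 - p.l3))
    assert np.max(np.abs(np.diff(y))) < max_slope * (x[1] - x[0]) * 1.01
    assert y.min() >= 0 and y.max() == 1.0


# -- force-velocity -----------------------------------------------------------

def test_force_velocity_examples():
    sol = load_fixture("sol")
    assert force_velocity(0.0, sol) == 1.0
    assert force_velocity(sol.v_CCmax, sol) == 0.0
    assert force_velocity(3.2, sol) == pytest.approx((6.4 - 3.2) / (6.4 + 3.2 / 0.15), rel=1e-12)
    assert force_velocity(2 * sol.v_CCmax, sol) == 0.0


def test_inverse_force_velocity_examples():
    sol = load_fixture("sol")
    assert inverse_force_velocity(1.0, sol) == pytest.approx(0.0, abs=1e-12)
    assert inverse_force_velocity(0.0, sol) == pytest.approx(sol.v_CCmax)
    assert inverse_force_velocity(0.1154, sol) == pytest.approx(3.2, abs=1e-3)
    v, saturated = inverse_force_velocity(2.0, sol, with_flag=True)
    assert saturated and v == pytest.approx(-sol.v_CCmax)


@pytest.mark.parametrize("name", ALL)
def test_force_velocity_roundtrip_grid(name):
    """force_velocity o inverse_force_velocity = identity to 1e-10 on a grid."""
    p = load_fixture(name)
    f = np.linspace(1e-6, 1.0, 100)
    v = inverse_force_velocity(f, p)
    assert np.max(np.abs(force_velocity(v, p) - f)) < 1e-10
    # eccentric branch too
    fe = np.linspace(1.0, p.f_v_ecc_max - 1e-6, 50)
    ve = inverse_force_velocity(fe, p)
    assert np.max(np.abs(force_velocity(ve, p) - fe)) < 1e-10


@given(st.floats(0.05, 0.95), st.floats(2.0, 20.0), st.floats(0.05, 2.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_force_velocity_strictly_decreasing(frac, vmax, curv):
    p = load_fixture("gas").with_(v_CCmax=vmax, curv=curv)
    v = np.linspace(0, vmax, 200)
    y = force_velocity(v, p)
    assert np.all(np.diff(y) < 0)
    assert force_velocity(frac * vmax, p) < 1.0


# -- activation ---------------------------------------------------------------

def test_activation_closed_form():
    assert activation(0.0, 0.06) == 0.0
    assert activation(0.06, 0.06) == pytest.approx(1 - math.exp(-1), rel=1e-12)
    assert activation(0.18, 0.06) == pytest.approx(0.9502, abs=1e-4)
    with pytest.raises(ParameterError):
        activation(0.1, -1.0)


# -- SEC ----------------------------------------------------------------------

@pytest.mark.parametrize("name", ALL)
def test_sec_transition_point(name):
    p = load_fixture(name)
    assert sec_force(p.dlSEC1, p) == pytest.approx(p.F1, rel=1e-9)
    assert sec_force(0.0, p) == 0.0
    assert sec_force(-1.0, p) == 0.0


def test_sec_half_transition_example():
    gas = load_fixture("gas")
    expected = gas.F1 * (math.exp(1.1) - 1) / (math.exp(2.2) - 1)
    assert sec_force(gas.dlSEC1 / 2, gas) == pytest.approx(expected, rel=1e-12)
    assert expected / gas.F1 == pytest.approx(0.2498, abs=2e-4)


def test_sec_linear_stiffness_continuity():
    """Derived k equals the numerical slope of the exponential branch at dlSEC1."""
    for name in ALL:
        p = load_fixture(name)
        k = sec_linear_stiffness(p)
        h = 1e-7
        slope = (sec_force(p.dlSEC1, p) - sec_force(p.dlSEC1 - h, p)) / h
        assert k == pytest.approx(slope, rel=1e-5)
    gas = load_fixture("gas")
    assert sec_linear_stiffness(gas) == pytest.approx(23.98, abs=0.02)


def test_sec_stiffness_linear_limit_and_scaling():
    gas = load_fixture("gas")
    near_zero = gas.with_(k_sh=1e-10)
    assert sec_linear_stiffness(near_zero) == pytest.approx(near_zero.F1 / near_zero.dlSEC1, rel=1e-6)
    doubled = gas.with_(F_im=2 * gas.F_im)
    assert sec_linear_stiffness(doubled) == pytest.approx(2 * sec_linear_stiffness(gas), rel=1e-12)


@pytest.mark.parametrize("name", ALL)
def test_sec_elongation_inverse(name):
    p = load_fixture(name)
    f = np.linspace(0, 1.5 * p.F_im, 300)
    assert np.max(np.abs(sec_force(sec_elongation(f, p), p) - f)) < 1e-8


# -- PEC ----------------------------------------------------------------------

def test_pec_force_examples():
    gas = load_fixture("gas")
    assert pec_force(0.0, gas) == 0.0
    assert pec_force(-1.0, gas) == 0.0
    assert pec_force(4.0, gas) == pytest.approx(0.048 * (math.exp(2.0) - 1), rel=1e-12)
    dl = np.linspace(0, 20, 100)
    assert np.all(np.diff(pec_force(dl, gas)) > 0)


# -- CC force and scalars -----------------------------------------------------

def test_cc_force_product_form():
    gas = load_fixture("gas")
    assert cc_force(0.0, 1.0, 0.0, gas) == 0.0
    assert cc_force(1.0, 1.0, 0.0, gas) == pytest.approx(161.3)
    assert cc_force(0.5, 1.0, 0.0, gas) == pytest.approx(gas.F_im / 2)


def test_cc_force_scales_with_fim():
    gas = load_fixture("gas")
    doubled = gas.with_(F_im=2 * gas.F_im)
    for a, l, v in [(1.0, 0.9, 2.0), (0.3, 1.1, 0.0), (0.7, 1.0, 5.0)]:
        assert cc_force(a, l, v, doubled) == pytest.approx(2 * cc_force(a, l, v, gas), rel=1e-12)


def test_csa_and_stress_printed_values():
    """CSA and mean stress from mass, density and optimal fiber length."""
    expected = {"gas": (8.63, 18.9), "pla": (4.57, 18.8), "sol": (1.44, 17.0)}
    for name, (csa_ref, stress_ref) in expected.items():
        csa, stress = csa_and_stress(load_fixture(name))
        assert csa == pytest.approx(csa_ref, rel=0.04)
        assert stress == pytest.approx(stress_ref, rel=0.04)


def test_csa_unit_construction():
    p = load_fixture("gas").with_(mass=1.056, l_CCopt=10.0)
    csa, _ = csa_and_stress(p)
    assert csa == pytest.approx(1.0, rel=1e-12)


def test_sol_sec_strain_at_fim():
    assert sec_strain_at_fim(load_fixture("sol")) == pytest.approx(0.036, rel=0.05)


# -- parameter records --------------------------------------------------------

def test_fixture_roundtrip_bit_exact(tmp_path):
    for name in ALL:
        p = load_fixture(name)
        path = tmp_path / f"{name}.toml"
        save_parameters(p, path)
        q = load_parameters(path)
        assert q == p


def test_invariant_validation():
    gas = load_fixture("gas")
    with pytest.raises(ParameterError):
        gas.with_(l1=0.9)           # breaks l1 < l2
    with pytest.raises(ParameterError):
        gas.with_(f_c=1.5)
    with pytest.raises(ParameterError):
        gas.with_(v_CCmax=-1.0)
    with pytest.raises(ParameterError):
        gas.with_(l_SEC0=0.0)


def test_unknown_key_rejected(tmp_path):
    path = tmp_path / "bad.toml"
    path.write_text('name = "X"\nbogus = 1.0\n')
    with pytest.raises(ParameterError):
        load_parameters(path)
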