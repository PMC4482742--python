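"""Forward contraction dynamics: statics consistency, clamps, conservation."""

import numpy as np
import pytest

from hillcalf.muscle_model import (
    force_length,
    force_velocity,
    load_fixture,
    pec_force,
    sec_force,
)
from hillcalf.contraction_simulator import (
    ProtocolSpec,
    ProtocolError,
    SimulationTrace,
    equilibrium_cc_length,
    force_balance_residual,
    optimal_mtc_length,
    passive_force_at_length,
    simulate,
    simulate_isometric_series,
)
from hillcalf.synthetic_experiments import (
    _isometric_protocol,
    _isotonic_protocol,
    _quick_release_protocol,
)


# -- protocol validation ------------------------------------------------------

def test_protocol_validation():
    with pytest.raises(ProtocolError):
        ProtocolSpec(mode="isokinetic_ramp", l_MTC_start=100.0)  # missing ramp fields
    with pytest.raises(ProtocolError):
        ProtocolSpec(mode="isometric", l_MTC_start=100.0, afterload=5.0)
    with pytest.raises(ProtocolError):
        ProtocolSpec(mode="isotonic_afterload", l_MTC_start=100.0)
    with pytest.raises(ProtocolError):
        ProtocolSpec(mode="isometric", l_MTC_start=100.0,
                     stimulation_on=0.5, stimulation_off=0.2)


# -- static equilibrium -------------------------------------------------------

def test_equilibrium_slack_chain():
    gas = load_fixture("gas")
    l_mtc = gas.l_SEC0 + 0.5 * gas.l_PEC0  # everything slack
    l_cc, slack = equilibrium_cc_length(l_mtc, 0.0, gas, full=True)
    assert slack
    assert l_cc == pytest.approx(l_mtc - gas.l_SEC0)
    assert passive_force_at_length(l_mtc, gas) == 0.0


@pytest.mark.parametrize("name", ["gas", "pla", "sol"])
def test_equilibrium_balances_forces(name):
    p = load_fixture(name)
    l_opt = optimal_mtc_length(p)
    for a in (0.0, 0.4, 1.0):
        l_cc = equilibrium_cc_length(l_opt, a, p)
        f_sec = sec_force(l_opt - l_cc - p.l_SEC0, p)
        f_cc = a * p.F_im * force_length(l_cc / p.l_CCopt, p)
        f_pec = pec_force(l_cc - p.l_PEC0, p)
        assert abs(f_sec - f_cc - f_pec) < 1e-6


def test_equilibrium_at_optimum_by_construction():
    gas = load_fixture("gas")
    l_opt = optimal_mtc_length(gas)
    assert equilibrium_cc_length(l_opt, 1.0, gas) == pytest.approx(gas.l_CCopt, abs=1e-6)


def test_equilibrium_force_monotone_in_length():
    gas = load_fixture("gas")
    l_opt = optimal_mtc_length(gas)
    lengths = np.linspace(l_opt - 12, l_opt, 7)
    forces = []
    for l_mtc in lengths:
        l_cc = equilibrium_cc_length(l_mtc, 1.0, gas)
        forces.append(sec_force(l_mtc - l_cc - gas.l_SEC0, gas))
    assert np.all(np.diff(forces) > 0)


# -- dynamic protocols --------------------------------------------------------

@pytest.mark.parametrize("name", ["gas", "sol"])
def test_isometric_steady_state_matches_statics(name):
    p = load_fixture(name)
    l_opt = optimal_mtc_length(p)
    tr = simulate(_isometric_protocol(l_opt, 1000.0, "t"), p)
    i = int(np.argmin(np.abs(tr.t - 0.79)))
    l_cc = equilibrium_cc_length(l_opt, 1.0, p)
    f_static = sec_force(l_opt - l_cc - p.l_SEC0, p)
    assert tr.F_total[i] == pytest.approx(f_static, rel=0.005)


def test_isotonic_plateau_velocity_on_hyperbola():
    """During the force clamp the corrected (force, speed) pair lies on Eq 3."""
    gas = load_fixture("gas")
    l_opt = optimal_mtc_length(gas)
    tr = simulate(_isotonic_protocol(l_opt, 0.5 * gas.F_im, 1000.0, "t"), gas)
    m = (tr.t > 0.462) & (tr.t < 0.52)
    v = -np.gradient(tr.l_CC, tr.t)[m] / gas.l_CCopt
    phi = (tr.F_total[m] - tr.F_PEC[m]) / (gas.F_im * force_length(tr.l_CC[m] / gas.l_CCopt, gas))
    assert np.max(np.abs(phi - force_velocity(v, gas))) < 5e-3
    assert np.max(np.abs(tr.F_total[m] - 0.5 * gas.F_im)) < 1e-6


def test_isotonic_afterload_above_max_rejected():
    gas = load_fixture("gas")
    with pytest.raises(ProtocolError):
        simulate(_isotonic_protocol(optimal_mtc_length(gas), 2.0 * gas.F_im, 1000.0, "t"), gas)


def test_quick_release_sec_absorbs_most_of_the_ramp():
    """With the lever twice as fast as the CC limit, the SEC takes >= half."""
    sol = load_fixture("sol")
    tr = simulate(_quick_release_protocol(sol, 1000.0), sol)
    proto = tr.meta["protocol"]
    i0 = int(np.searchsorted(tr.t, proto.ramp_start))
    i1 = i0 + int(np.argmax(tr.F_total[i0:] <= 1e-6))
    lever_drop = tr.l_MTC[i0] - tr.l_MTC[i1]
    sec_drop = tr.dl_SEC[i0] - tr.dl_SEC[i1]
    assert sec_drop >= 0.5 * lever_drop > 0


def test_force_clamp_holds_afterload():
    sol = load_fixture("sol")
    load = 0.3 * sol.F_im
    tr = simulate(_isotonic_protocol(optimal_mtc_length(sol), load, 1000.0, "t"), sol)
    m = (tr.t > 0.455) & (tr.t < 0.6)
    assert np.max(np.abs(tr.F_total[m] - load)) < 1e-3 * sol.F_im


@pytest.mark.parametrize("name", ["gas", "pla", "sol"])
def test_force_balance_identity_everywhere(name, clean_sets):
    """|F_SEC - F_CC - F_PEC| < 1e-4 N wherever the balance is attainable;
    unattainable samples are flagged and only occur at ~zero lever force."""
    p = load_fixture(name)
    for key, tr in clean_sets[name].traces.items():
        res = force_balance_residual(tr, p)
        assert np.max(np.abs(res[~tr.sat])) < 1e-4, key
        if tr.sat.any():
            assert np.max(tr.F_total[tr.sat]) < 0.0025 * p.F_im


def test_chain_geometry_identity(clean_sets):
    gas = load_fixture("gas")
    for tr in clean_sets["gas"].traces.values():
        assert np.max(np.abs(tr.l_MTC - (gas.l_SEC0 + tr.dl_SEC + tr.l_CC))) < 1e-6


def test_integrator_step_convergence():
    """Halving the maximum integrator step changes terminal force < 0.1%."""
    gas = load_fixture("gas")
    proto = _isometric_protocol(optimal_mtc_length(gas), 1000.0, "t")
    tr1 = simulate(proto, gas)
    tr2 = simulate(proto, gas, max_step=min(5e-3, gas.tau / 4.0) / 2.0)
    i = int(np.argmin(np.abs(tr1.t - 0.79)))
    assert tr2.F_total[i] == pytest.approx(tr1.F_total[i], rel=1e-3)


def test_isometric_series_truncates_at_passive_cap():
    gas = load_fixture("gas")
    l_opt = optimal_mtc_length(gas)
    lengths = list(np.arange(l_opt - 10, l_opt + 20, 2.0))
    series = simulate_isometric_series(lengths, gas)
    assert 0 < len(series) < len(lengths)
    for l_mtc, f_act, f_pass in series:
        assert f_pass <= 0.2 * gas.F_im
        assert f_act >= f_pass - 1e-9


@pytest.mark.parametrize("name", ["gas", "pla", "sol"])
def test_isometric_series_at_optimum_reaches_fim(name):
    """At the optimum the steady force minus the PEC contribution at the
    active CC length equals F_im; the naive active-minus-passive
    subtraction is biased because the CC sits longer when passive."""
    p = load_fixture(name)
    l_opt = optimal_mtc_length(p)
    [(l, f_act, f_pass)] = simulate_isometric_series([l_opt], p)
    l_cc = equilibrium_cc_length(l_opt, 1.0, p)
    assert f_act - pec_force(l_cc - p.l_PEC0, p) == pytest.approx(p.F_im, rel=0.01)
    assert f_act - f_pass == pytest.approx(p.F_im, rel=0.08)  # biased variant


def test_trace_csv_roundtrip(tmp_path, clean_sets):
    tr = clean_sets["sol"].traces["tetanus"]
    path = tmp_path / "trace.csv"
    tr.to_csv(path)
    back = SimulationTrace.from_csv(path)
    assert np.allclose(back.F_total, tr.F_total)
    assert np.allclose(back.l_MTC, tr.l_MTC)
    assert back.stim.dtype == bool
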