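"""Core model: transfer, STP steady states, rest state, state invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import stprnn as sp
from stprnn.model import steady_state_for_rates

from oracles import clamped_stp_integration, rhs_6d
from scipy.integrate import solve_ivp


@pytest.mark.parametrize("h, theta, expected", [
    (0.3, 0.3, 0.0),     # exactly at threshold
    (0.0, 0.3, 0.0),     # below threshold clamps to zero
    (5.3, 0.3, 5.0),     # unit gain above threshold
    (-2.0, 0.3, 0.0),
])
def test_transfer_threshold_linear(h, theta, expected):
    pop = sp.PopulationParams(tau=0.045, theta=theta, J=3.7,
                              stp=sp.PresynapticSTPParams(0.9, 5.5, 0.8))
    assert sp.transfer(h, pop) == pytest.approx(expected, abs=1e-15)


def test_transfer_rejects_non_finite():
    pop = sp.load_stage("P3").E
    for bad in (np.nan, np.inf, -np.inf):
        with pytest.raises(ValueError):
            sp.transfer(bad, pop)


@given(h=st.floats(-100, 100), d=st.floats(1e-6, 10))
def test_transfer_is_nonnegative_and_unit_slope_above_threshold(h, d):
    pop = sp.load_stage("P10").E
    f = sp.transfer(h, pop)
    assert f >= 0.0
    if h > pop.theta:
        assert sp.transfer(h + d, pop) - f == pytest.approx(d, rel=1e-9)


@pytest.mark.parametrize("kwargs", [
    dict(U=0.0, tau_r=1.0, tau_f=1.0),
    dict(U=1.5, tau_r=1.0, tau_f=1.0),
    dict(U=0.5, tau_r=0.0, tau_f=1.0),
    dict(U=0.5, tau_r=1.0, tau_f=-1.0),
])
def test_degenerate_stp_parameters_rejected(kwargs):
    with pytest.raises(ValueError):
        sp.PresynapticSTPParams(**kwargs)


def test_degenerate_population_parameters_rejected():
    stp = sp.PresynapticSTPParams(0.9, 5.5, 0.8)
    with pytest.raises(ValueError):
        sp.PopulationParams(tau=0.0, theta=0.3, J=3.7, stp=stp)
    with pytest.raises(ValueError):
        sp.PopulationParams(tau=0.045, theta=0.3, J=-1.0, stp=stp)


@pytest.mark.parametrize("stage", sp.STAGE_LABELS)
def test_rest_state_is_exact_zero_of_rhs(stages, stage):
    params = stages[stage]
    rest = sp.rest_state(params)
    dy = sp.rhs_full(0.0, rest.as_vector(), params)
    assert np.all(dy == 0.0)


def test_rest_state_values(stages):
    r3 = sp.rest_state(stages["P3"])
    assert r3.E_r == 0.0 and r3.I_r == 0.0
    assert np.all(r3.x == 1.0)
    assert np.allclose(r3.u, [0.9, 0.9, 0.9, 0.9])
    r20 = sp.rest_state(stages["P20"])
    # connection order EE, EI, IE, II: u starts at the presynaptic U
    assert np.allclose(r20.u, [0.55, 0.4, 0.55, 0.4])


def test_rest_state_requires_positive_threshold():
    p3 = sp.load_stage("P3")
    from dataclasses import replace
    bad = replace(p3, E=replace(p3.E, theta=0.0), stage="custom")
    with pytest.raises(ValueError, match="fixed point"):
        sp.rest_state(bad)


def test_zero_rate_limit_of_stp_dynamics(stages):
    """With silent populations the STP variables relax with their own
    time constants, independent of the rate equations."""
    params = stages["P10"]
    state = sp.rest_state(params)
    state.x = np.full(4, 0.5)
    state.u = np.full(4, 0.9)
    dy = sp.rhs_full(0.0, state.as_vector(), params)
    # P10: tau_r 3.0/2.5, tau_f 0.4/0.4, U 0.8/0.8
    expected_dx = [(1 - 0.5) / (3.0 if c in ("EE", "IE") else 2.5)
                   for c in sp.CONNECTIONS]
    expected_du = [(0.8 - 0.9) / 0.4 for _ in sp.CONNECTIONS]
    assert np.allclose(dy[2::2], expected_dx)
    assert np.allclose(dy[3::2], expected_du)


def test_stp_steady_state_closed_form_values():
    stp = sp.PresynapticSTPParams(U=0.9, tau_r=5.5, tau_f=0.8)
    u, x = sp.stp_steady_state(0.0, stp)
    assert (u, x) == (0.9, 1.0)
    u, x = sp.stp_steady_state(10.0, stp)
    assert u == pytest.approx(0.98780, abs=1e-5)
    assert x == pytest.approx(0.01807, abs=1e-5)
    with pytest.raises(ValueError):
        sp.stp_steady_state(-1.0, stp)


@pytest.mark.parametrize("stage", sp.STAGE_LABELS)
@pytest.mark.parametrize("pop", ["E", "I"])
def test_stp_steady_state_matches_clamped_integration(stages, stage, pop):
    stp = stages[stage].population(pop).stp
    for A in (0.0, 1.0, 5.0, 10.0, 50.0):
        u_a, x_a = sp.stp_steady_state(A, stp)
        u_n, x_n = clamped_stp_integration(stp, A)
        assert u_a == pytest.approx(u_n, abs=1e-6)
        assert x_a == pytest.approx(x_n, abs=1e-6)


def test_stp_steady_state_monotone_in_rate():
    stp = sp.load_stage("P14").E.stp
    A = np.linspace(0.0, 100.0, 2001)
    u, x = sp.stp_steady_state(A, stp)
    assert np.all(np.diff(u) > 0.0)
    assert np.all(np.diff(x) < 0.0)
    assert np.all((0.0 < x) & (x <= 1.0))
    assert np.all((stp.U <= u) & (u < 1.0))


def test_10d_matches_6d_presynaptic_reduction(stages):
    """STP parameters shared per presynaptic population make the EE/IE and
    EI/II variable pairs identical, so a 6D formulation must reproduce the
    10D trajectories."""
    params = stages["P3"]
    y0 = sp.rest_state(params).as_vector()
    y0[0] = 5.0  # rate perturbation, STP untouched
    kw = dict(method="LSODA", rtol=1e-12, atol=1e-14, dense_output=True)
    t_eval = np.linspace(0.0, 0.6, 61)
    full = solve_ivp(lambda t, y: sp.rhs_full(t, y, params), (0.0, 0.6), y0,
                     **kw)
    red = solve_ivp(rhs_6d, (0.0, 0.6), [5.0, 0.0, 1.0, 0.9, 1.0, 0.9],
                    args=(params,), **kw)
    yf = full.sol(t_eval)
    yr = red.sol(t_eval)
    # rates and the per-presynaptic-population STP variables
    assert np.max(np.abs(yf[0] - yr[0])) < 1e-9
    assert np.max(np.abs(yf[1] - yr[1])) < 1e-9
    assert np.max(np.abs(yf[2] - yr[2])) < 1e-9   # x_EE vs x_E
    assert np.max(np.abs(yf[4] - yr[4])) < 1e-9   # x_EI vs x_I
    assert np.max(np.abs(yf[6] - yr[2])) < 1e-9   # x_IE vs x_E
    assert np.max(np.abs(yf[3] - yr[3])) < 1e-9   # u_EE vs u_E


@pytest.mark.parametrize("stage", sp.STAGE_LABELS)
def test_trajectory_respects_state_bounds(impulse_trajs, stages, stage):
    traj = impulse_trajs[stage]
    y = traj.y
    assert np.min(y[0]) > -1e-9 and np.min(y[1]) > -1e-9
    x, u = y[2::2], y[3::2]
    assert np.all(x > 0.0) and np.all(x <= 1.0 + 1e-9)
    U = np.array([stages[stage].presynaptic_stp(c).U
                  for c in sp.CONNECTIONS])[:, None]
    assert np.all(u >= U - 1e-9) and np.all(u < 1.0)


def test_state_vector_roundtrip():
    state = steady_state_for_rates(3.0, 1.5, sp.load_stage("P14"))
    back = sp.NetworkState.from_vector(state.as_vector())
    assert back.E_r == state.E_r and back.I_r == state.I_r
    assert np.array_equal(back.x, state.x)
    assert np.array_equal(back.u, state.u)
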