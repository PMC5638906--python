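"""ISN / Non-ISN / unstable classification and domain-area metrics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import stprnn as sp
from stprnn.model import stp_steady_state, steady_state_for_rates
from stprnn.regimes import RegimeLabel, aod


@pytest.mark.parametrize("stage", sp.STAGE_LABELS)
def test_origin_is_non_isn(stages, stage):
    assert sp.classify_regime_point(0.0, 0.0, stages[stage]) \
        == RegimeLabel.NON_ISN


def test_p3_low_rate_axis_region_is_unstable(stages):
    """Immature networks: low-activity points just above the I_r = 0 axis
    sit in the unstable domain."""
    # the strip is confined to low rates: by E_r ~ 0.3 Hz synaptic
    # depression has already pulled the recurrent excitatory gain below 1
    for E in (0.05, 0.1, 0.2):
        assert sp.classify_regime_point(E, 0.0, stages["P3"]) \
            == RegimeLabel.UNSTABLE


def test_p20_low_rate_region_becomes_isn(stages):
    assert sp.classify_regime_point(1.0, 1.0, stages["P20"]) == RegimeLabel.ISN


def test_negative_rates_rejected(stages):
    with pytest.raises(ValueError):
        sp.classify_regime_point(-1.0, 0.0, stages["P3"])


def test_domain_map_is_an_exhaustive_partition(domain_maps):
    for dmap in domain_maps.values():
        counts = dmap.counts()
        assert sum(counts.values()) == dmap.labels.size
        total = sum(aod(dmap, lab) for lab in RegimeLabel)
        assert total == pytest.approx(dmap.box_area)


def test_domain_labels_invariant_to_thresholds(stages):
    """Doubling both thresholds must not move a single label."""
    from dataclasses import replace
    p = stages["P10"]
    doubled = replace(p, stage="custom",
                      E=replace(p.E, theta=2 * p.E.theta),
                      I=replace(p.I, theta=2 * p.I.theta))
    m1 = sp.fp_domain_map(p, resolution=41)
    m2 = sp.fp_domain_map(doubled, resolution=41)
    assert np.array_equal(m1.labels, m2.labels)


def test_aod_ratio_increases_and_non_isn_shrinks_across_development(
        domain_maps):
    ratios = [sp.aod_ratio(domain_map=domain_maps[s]) for s in sp.STAGE_LABELS]
    assert all(a < b for a, b in zip(ratios, ratios[1:]))
    non_isn = [aod(domain_maps[s], RegimeLabel.NON_ISN)
               for s in sp.STAGE_LABELS]
    assert all(a > b for a, b in zip(non_isn, non_isn[1:]))


def test_aod_stable_under_grid_refinement(stages, domain_maps):
    coarse = domain_maps["P10"]
    fine = sp.fp_domain_map(stages["P10"], resolution=201)
    for lab in RegimeLabel:
        drift = abs(aod(coarse, lab) - aod(fine, lab))
        assert drift < 0.01 * coarse.box_area


def test_stable_fixed_points_lie_in_stable_domains(stage_fps, stages):
    """Actual stable FPs must occupy ISN or Non-ISN cells; the new
    attractors after eye-opening operate in the ISN regime."""
    for stage, fps in stage_fps.items():
        for fp in fps:
            if not fp.stable:
                continue
            label = sp.classify_regime_point(fp.E_r, fp.I_r, stages[stage])
            assert label in (RegimeLabel.ISN, RegimeLabel.NON_ISN)
            if not fp.is_origin:
                assert label == RegimeLabel.ISN


def _clamped_E_subsystem_diverges(params, E0, I0, offset=1e-3, t_end=2.0):
    """Behavioural oracle for criterion A: with I_r clamped and the point
    made an equilibrium by a suitable constant drive, does a small rate
    offset grow or decay?  Returns True/False, or None if undecided."""
    uE, xE = stp_steady_state(E0, params.E.stp)
    uI, xI = stp_steady_state(I0, params.I.stp)
    drive_EI = params.I.J * uI * xI * I0
    # constant input making (E0, x*, u*) an equilibrium of the subsystem
    e_E = E0 + params.E.theta - (params.E.J * uE * xE * E0 - drive_EI)

    def rhs(t, y):
        E, x, u = y
        h = params.E.J * u * x * E - drive_EI + e_E
        f = params.E.G * (h - params.E.theta)  # active side by construction
        return [(-E + f) / params.E.tau,
                (1.0 - x) / params.E.stp.tau_r - u * x * E,
                (params.E.stp.U - u) / params.E.stp.tau_f
                + params.E.stp.U * (1.0 - u) * E]

    sol = solve_ivp(rhs, (0.0, t_end), [E0 + offset, xE, uE],
                    method="LSODA", rtol=1e-8, atol=1e-10)
    dev = abs(sol.y[0, -1] - E0)
    if not np.isfinite(dev) or dev > 3.0 * offset:
        return True
    if dev < offset / 3.0:
        return False
    return None


@pytest.mark.parametrize("stage", sp.STAGE_LABELS)
def test_criterion_a_agrees_with_clamped_integration(stages, stage):
    """Spectral criterion A (instability of the excitatory side at clamped
    inhibition) is checked behaviourally on random plane points."""
    rng = np.random.default_rng(20260927)
    params = stages[stage]
    decided = 0
    for _ in range(50):
        E0 = float(rng.uniform(0.05, 10.0))
        I0 = float(rng.uniform(0.0, 10.0))
        state = steady_state_for_rates(E0, I0, params)
        J = sp.model.jacobian_full(state.as_vector(), params,
                                   active_E=True, active_I=I0 > 0)
        sub = J[np.ix_([0, 2, 3], [0, 2, 3])]
        spectral_unstable = np.linalg.eigvals(sub).real.max() > 1e-10
        behavioural = _clamped_E_subsystem_diverges(params, E0, I0)
        if behavioural is None:
            continue
        decided += 1
        assert behavioural == spectral_unstable, (stage, E0, I0)
    assert decided >= 30


def test_rates_only_subsystem_variant_is_available(stages):
    lab = sp.classify_regime_point(2.0, 1.0, stages["P10"],
                                   include_stp_in_subsystem=False)
    assert isinstance(lab, RegimeLabel)


def test_aod_ratio_infinite_when_unstable_domain_vanishes(stages):
    """A glutamatergic-blockade network has no unstable domain at all."""
    params = sp.apply_blockade(stages["P3"],
                               sp.BlockadeSpec(target="glutamatergic"))
    ratio = sp.aod_ratio(params, resolution=21)
    assert ratio == np.inf
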