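"""Fixed-point finding, nullclines and linear stability."""

import numpy as np
import pytest

import stprnn as sp
from stprnn.fixed_points import _residual
from stprnn.model import steady_state_for_rates

from oracles import finite_difference_jacobian, nullcline_intersections


def test_stage_fixed_point_census(stage_fps):
    """Mono-stability before eye-opening, bi-stability after."""
    for stage in ("P3", "P10"):
        fps = stage_fps[stage]
        stable = [fp for fp in fps if fp.stable]
        assert len(stable) == 1 and stable[0].is_origin
    for stage in ("P14", "P20"):
        fps = stage_fps[stage]
        stable = [fp for fp in fps if fp.stable]
        assert len(stable) >= 2
        assert any(not fp.is_origin for fp in stable)


def test_glut_blockade_leaves_only_the_origin(stages):
    for stage in sp.STAGE_LABELS:
        params = sp.apply_blockade(stages[stage],
                                   sp.BlockadeSpec(target="glutamatergic"))
        fps = sp.find_fixed_points(params)
        assert len(fps) == 1
        assert fps[0].is_origin and fps[0].stable


@pytest.mark.parametrize("stage", ["P3", "P14"])
def test_nullcline_points_satisfy_their_balance(stages, stage):
    ncE, ncI = sp.quasi_nullclines(stages[stage], resolution=101)
    for curve, which in ((ncE, "E"), (ncI, "I")):
        assert curve.points.size > 0
        res = [abs(_residual(which, E, I, stages[stage], sp.ZERO_INPUT))
               for E, I in curve.points]
        assert max(res) < 1e-6


def test_p3_nullclines_contain_the_axis_branches(stages):
    ncE, ncI = sp.quasi_nullclines(stages["P3"], resolution=51)
    tagsE = [tag for tag, _ in ncE.branches]
    tagsI = [tag for tag, _ in ncI.branches]
    assert "axis" in tagsE and "axis" in tagsI
    # the vertical branch of the E-curve spans E_r = 0
    axis_pts = ncE.points[dict(ncE.branches)["axis"]]
    assert np.all(axis_pts[:, 0] == 0.0)
    assert axis_pts[:, 1].max() == 10.0


@pytest.mark.parametrize("stage", ["P14", "P20"])
def test_nullcline_intersections_match_fixed_points(stages, stage_fps, stage):
    """Cross-validation: intersections located on the sampled curves agree
    with the root-finder's fixed points to 1e-4 Hz."""
    inter = nullcline_intersections(stages[stage])
    fps = [fp for fp in stage_fps[stage] if fp.E_r <= 3.0 and fp.I_r <= 3.0]
    assert len(inter) >= len(fps)
    for fp in fps:
        d = min(np.hypot(fp.E_r - E, fp.I_r - I) for E, I in inter)
        assert d < 1e-4


@pytest.mark.parametrize("stage", ["P3", "P14"])
def test_analytic_jacobian_matches_finite_differences(stages, impulse_trajs,
                                                      stage):
    params = stages[stage]
    candidates = [
        sp.rest_state(params).as_vector(),
        impulse_trajs[stage].state_at(0.05),
        steady_state_for_rates(2.0, 1.0, params).as_vector(),
    ]
    fun = lambda y: sp.rhs_full(0.0, y, params)
    for y in candidates:
        J_an = sp.model.jacobian_full(y, params)
        J_fd = finite_difference_jacobian(fun, y)
        assert np.max(np.abs(J_an - J_fd)) < 1e-6


def test_frozen_at_rest_has_hidden_unstable_fp_near_origin(stages,
                                                           impulse_trajs):
    params = stages["P3"]
    w = sp.freeze_at(impulse_trajs["P3"], 0.0)
    fps = sp.frozen_fixed_points(params, w, search_box=((0, 5), (0, 5)),
                                 n_seeds=11)
    stable = [fp for fp in fps if fp.stable]
    unstable = [fp for fp in fps if not fp.stable]
    assert len(stable) == 1 and stable[0].is_origin
    assert len(unstable) >= 1
    assert min(np.hypot(fp.E_r, fp.I_r) for fp in unstable) < 0.5


@pytest.mark.parametrize("t_freeze", [0.175, 1.0])
def test_hidden_unstable_fp_absent_after_peak_and_before_recovery(
        stages, impulse_trajs, t_freeze):
    """The near-origin unstable FP of the frozen system disappears past the
    burst peak and needs seconds of synaptic recovery to re-emerge."""
    params = stages["P3"]
    w = sp.freeze_at(impulse_trajs["P3"], t_freeze)
    fps = sp.frozen_fixed_points(params, w, search_box=((0, 5), (0, 5)),
                                 n_seeds=11)
    near_unstable = [fp for fp in fps
                     if not fp.stable and np.hypot(fp.E_r, fp.I_r) < 1.0]
    assert near_unstable == []


def test_zero_efficacies_give_single_stable_origin(stages):
    w = sp.FrozenEfficacies(w=np.zeros(4))
    fps = sp.frozen_fixed_points(stages["P3"], w, n_seeds=7)
    assert len(fps) == 1
    assert fps[0].is_origin and fps[0].stable


@pytest.mark.parametrize("stage", sp.STAGE_LABELS)
def test_eigenvalue_verdicts_confirmed_by_forward_integration(stages,
                                                              stage_fps,
                                                              stage):
    params = stages[stage]
    for fp in stage_fps[stage]:
        y0 = fp.state.as_vector().copy()
        y0[0] += 1e-3
        traj = sp.integrate(params, sp.NetworkState.from_vector(y0),
                            t_span=(0.0, 2.0), validate=False)
        dist = np.hypot(traj.y[0] - fp.E_r, traj.y[1] - fp.I_r)
        if fp.stable:
            assert dist[-1] < 1e-3
        else:
            assert np.max(dist) > 1e-2


def test_fixed_points_have_small_residual_and_spectra(stage_fps, stages):
    for stage, fps in stage_fps.items():
        for fp in fps:
            res = np.max(np.abs(sp.rhs_full(0.0, fp.state.as_vector(),
                                            stages[stage])))
            assert res < 1e-8
            assert fp.eigenvalues is not None and fp.eigenvalues.size == 10
            assert fp.stable == bool(fp.eigenvalues.real.max() < -1e-10)
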