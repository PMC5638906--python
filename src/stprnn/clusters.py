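"""Detection and quantification of network-burst ("cluster") activity.

A cluster is a transient network spike involving both populations, evoked
from the quiescent state by a perturbation.  Its size proxy is

    PS_net_amp = omega * (A_sum_peak - A_sum_baseline),   A_sum = E_r + I_r

with omega = 1 by convention, and its duration runs from the perturbation
onset to the first time the summed activity comes within ``eps_term`` of the
terminal fixed point's summed activity.  Mono-stable clusters terminate back
at the quiescent state; bi-stable clusters terminate on a higher-activity
attractor.

The termination tolerance ``eps_term`` = 1 Hz is a fixed convention of this
package, calibrated once against the immature-stage (P3) burst duration of
roughly 330 ms under the standard impulse protocol and then frozen; all
other durations are predictions under the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import FrozenEfficacies, StageParameters, rest_state
from .simulate import (IMPULSE_AMPLITUDE, IMPULSE_WIDTH, Trajectory,
                       apply_impulse, freeze_at, integrate, integrate_frozen,
                       run_impulse_protocol)

__all__ = [
    "ClusterEvent",
    "PerturbationDomainMap",
    "detect_cluster",
    "ps_net_amp",
    "perturbation_domain_map",
    "amplification_threshold",
    "recovery_curve",
]

EPS_DETECT = 0.5   # Hz above baseline needed to call a cluster
EPS_TERM = 1.0     # Hz proximity to the terminal state that ends a cluster
SAMPLE_DT = 5e-5   # s; resampling step for peak/termination detection
RUNAWAY_A = 1e6    # Hz; summed activity beyond this is a runaway


@dataclass
class ClusterEvent:
    """One detected (or absent) cluster on a trajectory."""

    type: str                       # mono_stable | bi_stable | none | runaway
    onset: float
    peak_time: float | None = None
    termination: float | None = None
    A_sum_peak: float | None = None
    A_sum_baseline: float = 0.0
    terminal_rates: tuple[float, float] | None = None

    @property
    def duration(self) -> float | None:
        if self.termination is None:
            return None
        return self.termination - self.onset


def _perturbation_time(traj: Trajectory) -> float:
    for (t, label) in traj.events:
        if label == "impulse":
            return float(t)
    raise ValueError("trajectory carries no perturbation event marker")


def detect_cluster(traj: Trajectory, eps_det: float = EPS_DETECT,
                   eps_term: float = EPS_TERM,
                   sample_dt: float = SAMPLE_DT) -> ClusterEvent:
    """Locate and classify the cluster evoked by the trajectory's perturbation.

    Onset is the perturbation time; the baseline is the summed activity just
    before it (for a state-reset perturbation the injected rate is excluded
    by using the recorded pre-perturbation baseline).  Termination is the
    first time after the peak at which the summed activity enters the
    ``eps_term`` band around the terminal fixed point's summed activity.
    """
    onset = _perturbation_time(traj)
    t0, t1 = traj.t_span
    if traj.meta.get("runaway") or not np.all(np.isfinite(traj.y)):
        return ClusterEvent(type="runaway", onset=onset)

    baseline = traj.meta.get("baseline_a_sum")
    if baseline is None:
        baseline = float(traj.a_sum(max(t0, onset - 1e-9)))

    tg = np.arange(onset, t1, sample_dt)
    a = traj.a_sum(tg)
    if np.max(a) > RUNAWAY_A:
        return ClusterEvent(type="runaway", onset=onset,
                            A_sum_baseline=baseline)

    # exclude the perturbation itself (the injected rate, or the direct
    # response during an input pulse) from the peak search
    width = traj.meta.get("protocol", {}).get("width", 0.0) \
        if traj.meta.get("protocol", {}).get("mode") == "pulse" else 0.0
    after = tg > onset + width
    peak_idx = np.flatnonzero(after)[np.argmax(a[after])]
    peak, peak_t = float(a[peak_idx]), float(tg[peak_idx])

    terminal_state = traj.state_at(t1)
    terminal = (float(terminal_state[0]), float(terminal_state[1]))
    a_term = terminal[0] + terminal[1]

    # a cluster is a regenerative event: the network must amplify the
    # perturbation, not merely relax from it
    monotone_decay = bool(np.all(np.diff(a[after]) <= 1e-9))
    if peak < baseline + eps_det or monotone_decay:
        return ClusterEvent(type="none", onset=onset, peak_time=peak_t,
                            A_sum_peak=peak, A_sum_baseline=baseline,
                            terminal_rates=terminal)

    inside = np.abs(a - a_term) < eps_term
    rel = np.flatnonzero(inside[peak_idx:])
    termination = float(tg[peak_idx + rel[0]]) if rel.size else None

    kind = "mono_stable" if a_term < eps_det else "bi_stable"
    return ClusterEvent(type=kind, onset=onset, peak_time=peak_t,
                        termination=termination, A_sum_peak=peak,
                        A_sum_baseline=baseline, terminal_rates=terminal)


def ps_net_amp(traj: Trajectory, omega: float = 1.0, **detect_kwargs) -> float:
    """Cluster size proxy: omega * (peak summed activity - baseline).

    Returns 0 when no cluster is detected.
    """
    ev = detect_cluster(traj, **detect_kwargs)
    if ev.type in ("none",) or ev.A_sum_peak is None:
        return 0.0
    return omega * (ev.A_sum_peak - ev.A_sum_baseline)


@dataclass
class PerturbationDomainMap:
    """Amplification vs non-amplification of rate-reset initial conditions."""

    E_grid: np.ndarray
    I_grid: np.ndarray
    amplification: np.ndarray       # boolean (nE, nI)
    stage: str

    def to_frame(self) -> pd.DataFrame:
        EE, II = np.meshgrid(self.E_grid, self.I_grid, indexing="ij")
        return pd.DataFrame({
            "E_r0": EE.ravel(), "I_r0": II.ravel(),
            "label": np.where(self.amplification.ravel(),
                              "amplification", "non_amplification"),
        })


def _amplifies(params: StageParameters, E0: float, I0: float,
               growth: float, t_end: float, **options) -> bool:
    state = rest_state(params)
    state.E_r, state.I_r = float(E0), float(I0)
    traj = integrate(params, state, t_span=(0.0, t_end), **options)
    a0 = E0 + I0
    if a0 <= 0.0:
        return False
    return bool(np.max(traj.a_sum()) > growth * a0)


def perturbation_domain_map(params: StageParameters,
                            box: tuple[tuple[float, float], tuple[float, float]] =
                            ((0.0, 10.0), (0.0, 10.0)),
                            resolution: int = 21, growth: float = 1.5,
                            t_end: float = 2.0,
                            **options) -> PerturbationDomainMap:
    """Map rate-reset initial conditions to amplification behaviour.

    Each lattice point is used as the initial rates of a network whose STP
    variables start at their rest values; the point is an amplification
    point when the summed activity transiently exceeds ``growth`` times its
    initial value before settling.
    """
    (E_lo, E_hi), (I_lo, I_hi) = box
    E_grid = np.linspace(E_lo, E_hi, resolution)
    I_grid = np.linspace(I_lo, I_hi, resolution)
    amp = np.zeros((resolution, resolution), dtype=bool)
    for i, E0 in enumerate(E_grid):
        for j, I0 in enumerate(I_grid):
            amp[i, j] = _amplifies(params, E0, I0, growth, t_end, **options)
    return PerturbationDomainMap(E_grid=E_grid, I_grid=I_grid,
                                 amplification=amp, stage=params.stage)


def _frozen_escapes(params: StageParameters, w, E0: float, I0: float,
                    t_end: float = 2.0, bound: float = 1e4) -> bool:
    """Does the frozen-efficacy system leave the rest state's attraction
    domain from these initial rates?"""
    traj = integrate_frozen(params, w, (E0, I0), t_span=(0.0, t_end),
                            runaway_bound=bound)
    if traj.meta.get("runaway"):
        return True
    E1, I1 = traj.y[0, -1], traj.y[1, -1]
    return bool(np.hypot(E1, I1) > 1.0)


def amplification_threshold(params: StageParameters, n_rays: int = 24,
                            r_max: float = 30.0, tol: float = 1e-3,
                            t_end: float = 2.0) -> pd.DataFrame:
    """Boundary of the rest state's attraction domain in the frozen system.

    Efficacies are frozen at rest.  Along rays from the origin the escape /
    return behaviour is bisected to ``tol`` (Hz).  Rays that never escape
    within ``r_max`` are flagged open.

    Returns a DataFrame with columns angle (rad), radius, E_r, I_r, open.
    """
    rest = rest_state(params)
    w = FrozenEfficacies(
        w=np.array([params.E.J * rest.u[0] * rest.x[0],
                    params.I.J * rest.u[1] * rest.x[1],
                    params.E.J * rest.u[2] * rest.x[2],
                    params.I.J * rest.u[3] * rest.x[3]]),
        frozen_at=0.0)

    rows = []
    angles = np.linspace(0.0, np.pi / 2, n_rays)
    for ang in angles:
        dE, dI = np.cos(ang), np.sin(ang)
        lo, hi = 0.0, r_max
        if not _frozen_escapes(params, w, dE * r_max, dI * r_max, t_end):
            rows.append({"angle": ang, "radius": np.nan, "E_r": np.nan,
                         "I_r": np.nan, "open": True})
            continue
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if _frozen_escapes(params, w, dE * mid, dI * mid, t_end):
                hi = mid
            else:
                lo = mid
        r = 0.5 * (lo + hi)
        rows.append({"angle": ang, "radius": r, "E_r": dE * r, "I_r": dI * r,
                     "open": False})
    return pd.DataFrame(rows)


def recovery_curve(params: StageParameters, delays: Sequence[float],
                   amplitude: float = IMPULSE_AMPLITUDE,
                   width: float = IMPULSE_WIDTH, settle: float = 1.5,
                   **options) -> pd.DataFrame:
    """Size of a second evoked cluster as a function of the inter-pulse delay.

    A first standard impulse evokes a cluster; after ``delay`` seconds a
    second identical impulse is delivered and its cluster size measured
    against the immediately preceding activity.  As the delay grows the
    depressed excitatory synapses recover (time constant tau_rE) and the
    second size approaches the first.

    Returns a DataFrame with columns delay, ps_second, ps_first.
    """
    delays = sorted(float(d) for d in delays)
    if any(d <= 0.0 for d in delays):
        raise ValueError("delays must be positive")
    first = ps_net_amp(run_impulse_protocol(params, amplitude, width,
                                            t_end=settle, **options))
    from .model import ExternalInput

    rows = []
    for d in delays:
        def e_E(t, a=amplitude, w=width, d=d):
            return a if (0.0 <= t < w) or (d <= t < d + w) else 0.0
        ext = ExternalInput(e_E=e_E, e_I=lambda t: 0.0,
                            description=f"double impulse, delay {d} s",
                            breakpoints=(0.0, width, d, d + width))
        traj = integrate(params, rest_state(params), ext,
                         t_span=(0.0, d + settle), **options)
        baseline = float(traj.a_sum(d - 1e-6))
        tg = np.arange(d + width, d + settle, SAMPLE_DT)
        peak = float(np.max(traj.a_sum(tg)))
        rows.append({"delay": d, "ps_second": max(peak - baseline, 0.0),
                     "ps_first": first})
    return pd.DataFrame(rows)
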