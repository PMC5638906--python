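"""Deterministic integration of the full and frozen-efficacy systems.

The integrator is a stiff-capable adaptive solver (LSODA) with tight
tolerances and dense output.  External inputs may be discontinuous; the time
span is split at every declared input breakpoint so each segment sees a
smooth right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (CONNECTIONS, STATE_LABELS, ExternalInput, FrozenEfficacies,
                    NetworkState, StageParameters, ZERO_INPUT, rest_state,
                    rhs_frozen, rhs_full)

__all__ = [
    "Trajectory",
    "BlockadeSpec",
    "IntegrationError",
    "integrate",
    "integrate_frozen",
    "apply_impulse",
    "run_impulse_protocol",
    "freeze_at",
    "apply_blockade",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10

#: Standard impulse-perturbation protocol: a brief external pulse to the E
#: population delivered while the network rests at its quiescent state.
IMPULSE_AMPLITUDE = 30.0  # Hz
IMPULSE_WIDTH = 1e-3      # s


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid time."""

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(f"{message} (last valid time: {last_valid_time:.6g} s)")
        self.last_valid_time = last_valid_time


@dataclass
class Trajectory:
    """A dense solution of the network dynamics.

    ``t`` holds the solver's accepted time points and ``y`` the matching
    states, one column per time point.  ``state_at`` interpolates with the
    solver's own dense output, segment by segment.
    """

    t: np.ndarray
    y: np.ndarray                     # (dim, n)
    params: StageParameters
    input: ExternalInput
    events: list = field(default_factory=list)   # (time, label) markers
    meta: dict = field(default_factory=dict)
    _segments: list = field(default_factory=list, repr=False)

    @property
    def t_span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])

    def state_at(self, t) -> np.ndarray:
        """Interpolated state at time(s) ``t`` (columns for array input)."""
        tq = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.t_span
        if np.any(tq < lo - 1e-12) or np.any(tq > hi + 1e-12):
            raise ValueError(f"time out of range [{lo}, {hi}]")
        tq = np.clip(tq, lo, hi)
        out = np.empty((self.y.shape[0], tq.size))
        for i, ti in enumerate(tq):
            for (t0, t1, sol) in self._segments:
                if t0 - 1e-12 <= ti <= t1 + 1e-12:
                    out[:, i] = sol(min(max(ti, t0), t1))
                    break
            else:  # pragma: no cover - guarded by the range check above
                raise ValueError(f"no dense segment covers t={ti}")
        return out[:, 0] if np.ndim(t) == 0 else out

    def sample(self, n: int = 2001) -> tuple[np.ndarray, np.ndarray]:
        """Uniform resampling: (time grid, states)."""
        tg = np.linspace(*self.t_span, n)
        return tg, self.state_at(tg)

    def a_sum(self, t=None) -> np.ndarray:
        """Summed population activity E_r + I_r (Hz) at the solver points
        or at the requested times."""
        if t is None:
            return self.y[0] + self.y[1]
        s = self.state_at(t)
        return s[0] + s[1]

    def to_frame(self, n: int | None = None) -> pd.DataFrame:
        if n is None:
            t, y = self.t, self.y
        else:
            t, y = self.sample(n)
        labels = STATE_LABELS[:y.shape[0]] if y.shape[0] > 2 else ("E_r", "I_r")
        df = pd.DataFrame(dict(zip(labels, y)))
        df.insert(0, "t", t)
        df["e_E"] = [self.input.e_E(ti) for ti in t]
        df["e_I"] = [self.input.e_I(ti) for ti in t]
        return df

    def to_csv(self, path, n: int | None = 4001) -> None:
        self.to_frame(n).to_csv(path, index=False)


def _split_span(t_span, breakpoints):
    t0, t1 = t_span
    cuts = sorted(b for b in breakpoints if t0 < b < t1)
    edges = [t0, *cuts, t1]
    return list(zip(edges[:-1], edges[1:]))


def _integrate_segments(fun, t_span, y0, breakpoints, method, rtol, atol,
                        max_step, stop_events=None):
    t_parts, y_parts, segments = [], [], []
    y = np.asarray(y0, dtype=float)
    for (a, b) in _split_span(t_span, breakpoints):
        sol = solve_ivp(fun, (a, b), y, method=method, rtol=rtol, atol=atol,
                        max_step=max_step, dense_output=True,
                        events=stop_events)
        if sol.status == -1:
            raise IntegrationError(sol.message, sol.t[-1] if sol.t.size else a)
        t_parts.append(sol.t)
        y_parts.append(sol.y)
        segments.append((sol.t[0], sol.t[-1], sol.sol))
        y = sol.y[:, -1]
        if sol.status == 1:  # terminated by an event (e.g. runaway guard)
            break
    return np.concatenate(t_parts), np.hstack(y_parts), segments


def integrate(params: StageParameters, initial: NetworkState,
              input: ExternalInput = ZERO_INPUT,
              t_span: tuple[float, float] = (0.0, 2.0),
              method: str = "LSODA", rtol: float = DEFAULT_RTOL,
              atol: float = DEFAULT_ATOL, max_step: float = np.inf,
              validate: bool = True) -> Trajectory:
    """Integrate the full 10D system from an initial state.

    Returns a :class:`Trajectory` with dense output.  Identical arguments
    produce bit-identical results.
    """
    if validate:
        initial.validate(params)
    fun = lambda t, y: rhs_full(t, y, params, input)
    t, y, segments = _integrate_segments(
        fun, t_span, initial.as_vector(), input.breakpoints,
        method, rtol, atol, max_step)
    return Trajectory(t=t, y=y, params=params, input=input,
                      meta={"system": "full_10D", "rtol": rtol, "atol": atol},
                      _segments=segments)


def integrate_frozen(params: StageParameters, w: FrozenEfficacies,
                     initial_rates: tuple[float, float],
                     input: ExternalInput = ZERO_INPUT,
                     t_span: tuple[float, float] = (0.0, 2.0),
                     method: str = "LSODA", rtol: float = DEFAULT_RTOL,
                     atol: float = DEFAULT_ATOL,
                     runaway_bound: float = 1e6) -> Trajectory:
    """Integrate the 2D frozen-efficacy system.

    Growth is not bounded in this system (that is its point: without synaptic
    depression, threshold-crossing perturbations run away), so integration
    stops at ``runaway_bound`` and the trajectory is flagged.
    """
    fun = lambda t, r: rhs_frozen(t, r, params, w, input)

    def runaway(t, r):
        return max(abs(r[0]), abs(r[1])) - runaway_bound
    runaway.terminal = True

    t, y, segments = _integrate_segments(
        fun, t_span, np.asarray(initial_rates, dtype=float), input.breakpoints,
        method, rtol, atol, np.inf, stop_events=[runaway])
    traj = Trajectory(t=t, y=y, params=params, input=input,
                      meta={"system": "frozen_2D", "frozen_at": w.frozen_at,
                            "runaway": bool(t[-1] < t_span[1] - 1e-9)},
                      _segments=segments)
    return traj


def apply_impulse(state: NetworkState, amplitude: float,
                  population: str = "E") -> NetworkState:
    """Instantaneously reset one population's rate, leaving STP untouched."""
    if amplitude < 0.0:
        raise ValueError("impulse amplitude must be non-negative")
    new = state.copy()
    if population == "E":
        new.E_r = float(amplitude)
    elif population == "I":
        new.I_r = float(amplitude)
    else:
        raise ValueError("population must be 'E' or 'I'")
    return new


def run_impulse_protocol(params: StageParameters,
                         amplitude: float = IMPULSE_AMPLITUDE,
                         width: float = IMPULSE_WIDTH,
                         population: str = "E",
                         t_end: float = 3.0,
                         mode: str = "pulse",
                         **options) -> Trajectory:
    """The standard burst-evoking protocol from the quiescent state.

    A brief rectangular external pulse (``amplitude`` Hz for ``width`` s,
    default 30 Hz for 1 ms) is delivered to one population at t = 0 while
    the network rests at its stable quiescent state.  ``mode='reset'``
    instead sets the population rate itself to ``amplitude`` at t = 0, the
    convention used for perturbation-domain maps.
    """
    rest = rest_state(params)
    if mode == "pulse":
        if population == "E":
            ext = ExternalInput(
                e_E=lambda t, a=amplitude, w=width: a if 0.0 <= t < w else 0.0,
                e_I=lambda t: 0.0,
                description=f"impulse({amplitude} Hz, {width} s, E)",
                breakpoints=(0.0, width))
        else:
            ext = ExternalInput(
                e_E=lambda t: 0.0,
                e_I=lambda t, a=amplitude, w=width: a if 0.0 <= t < w else 0.0,
                description=f"impulse({amplitude} Hz, {width} s, I)",
                breakpoints=(0.0, width))
        initial = rest
    elif mode == "reset":
        ext = ZERO_INPUT
        initial = apply_impulse(rest, amplitude, population)
    else:
        raise ValueError("mode must be 'pulse' or 'reset'")

    traj = integrate(params, initial, ext, t_span=(0.0, t_end), **options)
    traj.events.append((0.0, "impulse"))
    traj.meta.update(
        baseline_a_sum=rest.E_r + rest.I_r,
        protocol={"amplitude": amplitude, "width": width,
                  "population": population, "mode": mode})
    return traj


def freeze_at(traj: Trajectory, t: float) -> FrozenEfficacies:
    """Capture the synaptic efficacies J*u*x of a trajectory at time ``t``."""
    y = traj.state_at(t)
    if y.shape[0] < 10:
        raise ValueError("can only freeze efficacies of a full 10D trajectory")
    J = {"E": traj.params.E.J, "I": traj.params.I.J}
    presyn = ("E", "I", "E", "I")
    w = np.array([J[p] * y[3 + 2 * k] * y[2 + 2 * k]
                  for k, p in enumerate(presyn)])
    return FrozenEfficacies(w=w, frozen_at=float(t))


@dataclass(frozen=True)
class BlockadeSpec:
    """A simulated receptor blockade.

    ``GABAergic`` zeroes the inhibitory efficacy J_I; ``glutamatergic``
    zeroes the excitatory efficacy J_E.
    """

    target: str = "none"
    applied_at: object = "from_start"

    def __post_init__(self) -> None:
        if self.target not in ("GABAergic", "glutamatergic", "none"):
            raise ValueError(
                "blockade target must be 'GABAergic', 'glutamatergic' or 'none'")


def apply_blockade(params: StageParameters, spec: BlockadeSpec) -> StageParameters:
    """Return the parameter set with the blocked efficacy set to zero."""
    if spec.target == "none":
        return params
    if spec.target == "GABAergic":
        return replace(params, stage=f"{params.stage}:gaba_block",
                       I=replace(params.I, J=0.0))
    return replace(params, stage=f"{params.stage}:glut_block",
                   E=replace(params.E, J=0.0))
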