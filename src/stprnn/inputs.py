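"""Seeded generators for the external-input protocols.

Three kinds of drive are supported: the standard brief *impulse* pulse, a
longer-lasting *step*, and sparse random *noise* events standing in for
spontaneous retinal-wave / thalamic input.  The noise model is deliberately
simple — exponentially distributed inter-event intervals with brief
rectangular events — because the biological referents are discrete,
well-separated events; its parameters are illustrative knobs, not measured
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .model import ExternalInput, StageParameters, rest_state
from .simulate import integrate

__all__ = [
    "InputSpec",
    "make_input",
    "spontaneous_event_statistics",
]


@dataclass(frozen=True)
class InputSpec:
    """Declarative description of an external-input protocol.

    Parameters
    ----------
    kind : {"impulse", "step", "noise"}
    target : {"E", "I", "both"}
        Which population receives the drive.
    amplitude : float
        Drive amplitude in Hz (mean amplitude for noise events).
    onset, offset : float
        Step window (s); impulse uses ``onset`` and ``width``.
    width : float
        Impulse / noise-event width (s).
    rate : float
        Mean noise-event rate (Hz).
    amplitude_sd : float
        Standard deviation of noise-event amplitudes (truncated at 0).
    horizon : float or None
        Time span over which noise events are generated.
    seed : int or None
        Seed for the noise generator; recorded in the input description.
    """

    kind: str
    target: str = "E"
    amplitude: float = 30.0
    onset: float = 0.0
    offset: float | None = None
    width: float = 1e-3
    rate: float = 0.25
    amplitude_sd: float = 0.0
    horizon: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("impulse", "step", "noise"):
            raise ValueError("kind must be 'impulse', 'step' or 'noise'")
        if self.target not in ("E", "I", "both"):
            raise ValueError("target must be 'E', 'I' or 'both'")
        if self.amplitude < 0.0:
            raise ValueError("amplitude must be non-negative")
        if self.kind == "step" and self.offset is not None \
                and not self.onset < self.offset:
            raise ValueError("step requires onset < offset")
        if self.kind == "noise":
            if self.rate <= 0.0 or self.width <= 0.0:
                raise ValueError("noise requires positive rate and width")
            if self.horizon is None:
                raise ValueError("noise requires a horizon")


def _piecewise(edges: np.ndarray, values: np.ndarray):
    """Right-continuous step function from sorted edges and level values."""
    def f(t, edges=edges, values=values):
        i = np.searchsorted(edges, t, side="right") - 1
        return float(values[i]) if i >= 0 else 0.0
    return f


def noise_events(spec: InputSpec) -> np.ndarray:
    """Event onset times of a noise spec (Poisson, seeded)."""
    rng = np.random.default_rng(spec.seed)
    times, t = [], 0.0
    while True:
        t += rng.exponential(1.0 / spec.rate)
        if t >= spec.horizon:
            break
        times.append(t)
    return np.asarray(times)


def make_input(spec: InputSpec) -> ExternalInput:
    """Realize an :class:`InputSpec` as a callable external input."""
    if spec.kind == "impulse":
        a, t0, w = spec.amplitude, spec.onset, spec.width
        f = lambda t: a if t0 <= t < t0 + w else 0.0
        breakpoints = (t0, t0 + w)
        desc = f"impulse({a} Hz, {w} s at t={t0}, {spec.target})"
    elif spec.kind == "step":
        a, t0, t1 = spec.amplitude, spec.onset, spec.offset
        if t1 is None:
            f = lambda t: a if t >= t0 else 0.0
            breakpoints = (t0,)
        else:
            f = lambda t: a if t0 <= t < t1 else 0.0
            breakpoints = (t0, t1)
        desc = f"step({a} Hz on [{t0}, {t1}), {spec.target})"
    else:
        rng = np.random.default_rng(spec.seed)
        onsets = noise_events(spec)
        amps = np.maximum(
            rng.normal(spec.amplitude, spec.amplitude_sd, size=onsets.size), 0.0) \
            if spec.amplitude_sd > 0 else np.full(onsets.size, spec.amplitude)
        # overlapping events sum; build the cumulative step profile
        edge_list = np.concatenate([onsets, onsets + spec.width])
        delta = np.concatenate([amps, -amps])
        order = np.argsort(edge_list, kind="stable")
        edges = edge_list[order]
        values = np.cumsum(delta[order])
        values[np.abs(values) < 1e-12] = 0.0
        f = _piecewise(edges, values)
        breakpoints = tuple(float(e) for e in edges)
        desc = (f"noise(rate={spec.rate} Hz, amp={spec.amplitude}"
                f"+-{spec.amplitude_sd} Hz, width={spec.width} s, "
                f"seed={spec.seed}, {spec.target})")

    zero = lambda t: 0.0
    e_E = f if spec.target in ("E", "both") else zero
    e_I = f if spec.target in ("I", "both") else zero
    return ExternalInput(e_E=e_E, e_I=e_I, description=desc,
                         breakpoints=breakpoints)


def spontaneous_event_statistics(params: StageParameters, noise_spec: InputSpec,
                                 horizon: float | None = None,
                                 seed: int | None = None,
                                 eps_det: float = 0.5,
                                 min_separation: float = 0.1) -> dict:
    """Cluster statistics under sparse random drive.

    Drives the network from rest with the realized noise input over the
    horizon, detects evoked clusters as peaks of the summed activity, and
    returns per-event sizes together with the preceding quiet intervals.
    Because depressed excitatory synapses need seconds to recover, event
    sizes grow with the length of the preceding quiet interval.

    Returns a dict with keys ``peak_times``, ``sizes``, ``intervals``
    (preceding inter-event interval per event, NaN for the first),
    ``n_events``, ``input_events`` and ``seed``.
    """
    updates = {}
    if horizon is not None:
        updates["horizon"] = horizon
    if seed is not None:
        updates["seed"] = seed
    if updates:
        from dataclasses import replace as _replace
        noise_spec = _replace(noise_spec, **updates)

    ext = make_input(noise_spec)
    traj = integrate(params, rest_state(params), ext,
                     t_span=(0.0, noise_spec.horizon))
    dt = 1e-3
    tg = np.arange(0.0, noise_spec.horizon, dt)
    a = traj.a_sum(tg)

    idx, _ = find_peaks(a, height=eps_det,
                        distance=max(int(min_separation / dt), 1))
    peak_times = tg[idx]
    sizes = []
    for k, i in enumerate(idx):
        lo = idx[k - 1] if k > 0 else 0
        baseline = float(np.min(a[lo:i + 1]))
        sizes.append(float(a[i]) - baseline)
    intervals = np.concatenate([[np.nan], np.diff(peak_times)]) \
        if idx.size else np.array([])
    return {
        "peak_times": np.asarray(peak_times),
        "sizes": np.asarray(sizes),
        "intervals": intervals,
        "n_events": int(idx.size),
        "input_events": noise_events(noise_spec),
        "seed": noise_spec.seed,
    }
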