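"""Core model: a two-population (E/I) rate network with dynamic synapses.

The network is a Wilson-Cowan-type mean-field model in which every recurrent
connection carries Tsodyks-Markram short-term plasticity (STP).  The state is
ten-dimensional: the two population rates ``E_r`` and ``I_r`` (Hz) plus a
depression variable ``x`` and a facilitation variable ``u`` for each of the
four connections EE, EI, IE, II (first index postsynaptic, second
presynaptic).  The rate equations are

    tau_E dE_r/dt = -E_r + f_E(J_E u_EE x_EE E_r - J_I u_EI x_EI I_r + e_E)
    tau_I dI_r/dt = -I_r + f_I(J_E u_IE x_IE E_r - J_I u_II x_II I_r + e_I)

with the threshold-linear transfer f_i(h) = G_i * max(0, h - theta_i), and
for every connection ij with presynaptic population j and presynaptic rate
A_j:

    dx_ij/dt = (1 - x_ij)/tau_r_j - u_ij x_ij A_j
    du_ij/dt = (U_j - u_ij)/tau_f_j + U_j (1 - u_ij) A_j

STP parameters (U, tau_r, tau_f) and the absolute efficacy J are properties
of the presynaptic population, so the EE and IE connections share the
excitatory values and EI and II the inhibitory ones.  The product
``J_j * u_ij * x_ij`` is the instantaneous synaptic efficacy; "freezing" it
turns the network into a two-dimensional static-efficacy rate model
(:func:`rhs_frozen`) whose hidden fixed points shape the onset of network
bursts.

All times are in seconds and all rates in Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "CONNECTIONS",
    "STATE_LABELS",
    "PresynapticSTPParams",
    "PopulationParams",
    "StageParameters",
    "NetworkState",
    "FrozenEfficacies",
    "ExternalInput",
    "ZERO_INPUT",
    "transfer",
    "rhs_full",
    "rhs_frozen",
    "stp_steady_state",
    "rest_state",
    "steady_state_for_rates",
    "jacobian_full",
    "jacobian_frozen",
]

#: Connection order used everywhere a per-connection array appears.
#: "EI" is the I -> E connection (postsynaptic E, presynaptic I).
CONNECTIONS: tuple[str, ...] = ("EE", "EI", "IE", "II")

#: Presynaptic population of each connection, aligned with CONNECTIONS.
_PRESYN: tuple[str, ...] = ("E", "I", "E", "I")

#: Labels of the 10 state-vector components, in order.
STATE_LABELS: tuple[str, ...] = (
    "E_r", "I_r",
    "x_EE", "u_EE", "x_EI", "u_EI", "x_IE", "u_IE", "x_II", "u_II",
)


@dataclass(frozen=True)
class PresynapticSTPParams:
    """Short-term plasticity parameters of one presynaptic population.

    Parameters
    ----------
    U : float
        Release probability, in (0, 1].  Baseline of the facilitation
        variable ``u``.
    tau_r : float
        Recovery time constant of synaptic depression (s), > 0.
    tau_f : float
        Facilitation time constant (s), > 0.
    """

    U: float
    tau_r: float
    tau_f: float

    def __post_init__(self) -> None:
        if not (0.0 < self.U <= 1.0):
            raise ValueError(f"release probability U must be in (0, 1], got {self.U}")
        if self.tau_r <= 0.0:
            raise ValueError(f"tau_r must be positive, got {self.tau_r}")
        if self.tau_f <= 0.0:
            raise ValueError(f"tau_f must be positive, got {self.tau_f}")


@dataclass(frozen=True)
class PopulationParams:
    """Rate-dynamics and outgoing-synapse parameters of one population.

    Parameters
    ----------
    tau : float
        Rate (membrane/synaptic filtering) time constant (s), > 0.
    theta : float
        Activity threshold of the threshold-linear transfer (Hz), >= 0.
    J : float
        Absolute efficacy of this population's outgoing synapses
        (dimensionless), >= 0.
    stp : PresynapticSTPParams
        Short-term plasticity of the outgoing synapses.
    G : float
        Linear input-output gain above threshold; fixed at 1 in the
        developmental parameterization.
    """

    tau: float
    theta: float
    J: float
    stp: PresynapticSTPParams
    G: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0.0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.theta < 0.0:
            raise ValueError(f"theta must be non-negative, got {self.theta}")
        if self.J < 0.0:
            raise ValueError(f"J must be non-negative, got {self.J}")
        if self.G < 0.0:
            raise ValueError(f"G must be non-negative, got {self.G}")


@dataclass(frozen=True)
class StageParameters:
    """Full parameter set of the network at one developmental stage."""

    stage: str
    E: PopulationParams
    I: PopulationParams

    def population(self, which: str) -> PopulationParams:
        if which == "E":
            return self.E
        if which == "I":
            return self.I
        raise ValueError(f"unknown population {which!r}, expected 'E' or 'I'")

    def presynaptic_stp(self, connection: str) -> PresynapticSTPParams:
        """STP parameter set governing a connection (by its presynaptic side)."""
        j = _PRESYN[CONNECTIONS.index(connection)]
        return self.population(j).stp


@lru_cache(maxsize=256)
def _flat(params: StageParameters) -> tuple[float, ...]:
    """Flatten a parameter set for fast access inside the RHS."""
    E, I = params.E, params.I
    return (
        E.tau, I.tau, E.theta, I.theta, E.G, I.G, E.J, I.J,
        E.stp.U, E.stp.tau_r, E.stp.tau_f,
        I.stp.U, I.stp.tau_r, I.stp.tau_f,
    )


@dataclass
class NetworkState:
    """The 10-dimensional dynamical state.

    ``x`` and ``u`` are length-4 arrays ordered as :data:`CONNECTIONS`.
    """

    E_r: float
    I_r: float
    x: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.x.shape != (4,) or self.u.shape != (4,):
            raise ValueError("x and u must each hold one value per connection (4)")

    def as_vector(self) -> np.ndarray:
        y = np.empty(10)
        y[0], y[1] = self.E_r, self.I_r
        y[2::2] = self.x
        y[3::2] = self.u
        return y

    @classmethod
    def from_vector(cls, y: Sequence[float]) -> "NetworkState":
        y = np.asarray(y, dtype=float)
        return cls(E_r=float(y[0]), I_r=float(y[1]),
                   x=y[2::2].copy(), u=y[3::2].copy())

    def copy(self) -> "NetworkState":
        return NetworkState(self.E_r, self.I_r, self.x.copy(), self.u.copy())

    def validate(self, params: StageParameters, atol: float = 1e-7) -> None:
        """Check the state invariants: non-negative rates, x in (0,1], u in [U,1)."""
        if self.E_r < -atol or self.I_r < -atol:
            raise ValueError("population rates must be non-negative")
        if np.any(self.x <= 0.0) or np.any(self.x > 1.0 + atol):
            raise ValueError("depression variables x must lie in (0, 1]")
        U = np.array([params.presynaptic_stp(c).U for c in CONNECTIONS])
        if np.any(self.u < U - atol) or np.any(self.u >= 1.0 + atol):
            raise ValueError("facilitation variables u must lie in [U, 1)")

    def rates(self) -> tuple[float, float]:
        return self.E_r, self.I_r


@dataclass(frozen=True)
class FrozenEfficacies:
    """Synaptic efficacies J*u*x captured at one instant, per connection."""

    w: np.ndarray  # length 4, CONNECTIONS order
    frozen_at: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))
        if self.w.shape != (4,):
            raise ValueError("w must hold one efficacy per connection (4)")
        if np.any(self.w < 0.0):
            raise ValueError("frozen efficacies must be non-negative")

    def __getitem__(self, connection: str) -> float:
        return float(self.w[CONNECTIONS.index(connection)])


@dataclass(frozen=True)
class ExternalInput:
    """Time-dependent external drives to the two populations (Hz).

    ``breakpoints`` lists times where either drive is discontinuous so that
    the integrator can split the time span there.
    """

    e_E: Callable[[float], float]
    e_I: Callable[[float], float]
    description: str = ""
    breakpoints: tuple[float, ...] = ()

    @classmethod
    def zero(cls) -> "ExternalInput":
        return cls(e_E=lambda t: 0.0, e_I=lambda t: 0.0, description="zero")

    @classmethod
    def constant(cls, e_E: float = 0.0, e_I: float = 0.0) -> "ExternalInput":
        return cls(e_E=lambda t: e_E, e_I=lambda t: e_I,
                   description=f"constant(e_E={e_E}, e_I={e_I})")


ZERO_INPUT = ExternalInput.zero()


def transfer(h: float, pop: PopulationParams) -> float:
    """Threshold-linear transfer: G*(h - theta) above threshold, else 0."""
    if not math.isfinite(h):
        raise ValueError(f"net input must be finite, got {h}")
    return pop.G * (h - pop.theta) if h > pop.theta else 0.0


def rhs_full(t: float, y: np.ndarray, params: StageParameters,
             ext: ExternalInput = ZERO_INPUT) -> np.ndarray:
    """Time derivative of the full 10D state.

    Layout of ``y`` follows :data:`STATE_LABELS`.
    """
    (tauE, tauI, thE, thI, GE, GI, JE, JI,
     UE, trE, tfE, UI, trI, tfI) = _flat(params)
    E, I = y[0], y[1]
    xEE, uEE, xEI, uEI, xIE, uIE, xII, uII = y[2:10]

    hE = JE * uEE * xEE * E - JI * uEI * xEI * I + ext.e_E(t)
    hI = JE * uIE * xIE * E - JI * uII * xII * I + ext.e_I(t)
    fE = GE * (hE - thE) if hE > thE else 0.0
    fI = GI * (hI - thI) if hI > thI else 0.0

    dy = np.empty(10)
    dy[0] = (-E + fE) / tauE
    dy[1] = (-I + fI) / tauI
    # connections: EE, EI, IE, II; presynaptic rate and STP per presyn pop
    dy[2] = (1.0 - xEE) / trE - uEE * xEE * E
    dy[3] = (UE - uEE) / tfE + UE * (1.0 - uEE) * E
    dy[4] = (1.0 - xEI) / trI - uEI * xEI * I
    dy[5] = (UI - uEI) / tfI + UI * (1.0 - uEI) * I
    dy[6] = (1.0 - xIE) / trE - uIE * xIE * E
    dy[7] = (UE - uIE) / tfE + UE * (1.0 - uIE) * E
    dy[8] = (1.0 - xII) / trI - uII * xII * I
    dy[9] = (UI - uII) / tfI + UI * (1.0 - uII) * I
    return dy


def rhs_frozen(t: float, r: np.ndarray, params: StageParameters,
               w: FrozenEfficacies, ext: ExternalInput = ZERO_INPUT) -> np.ndarray:
    """Time derivative of the 2D rate system with efficacies held constant."""
    wEE, wEI, wIE, wII = w.w
    E, I = r[0], r[1]
    hE = wEE * E - wEI * I + ext.e_E(t)
    hI = wIE * E - wII * I + ext.e_I(t)
    fE = transfer(hE, params.E)
    fI = transfer(hI, params.I)
    return np.array([(-E + fE) / params.E.tau, (-I + fI) / params.I.tau])


def stp_steady_state(A, stp: PresynapticSTPParams):
    """Steady-state facilitation and depression at a clamped presynaptic rate.

    Setting du/dt = 0 and dx/dt = 0 at a constant presynaptic rate ``A`` (Hz)
    gives

        u* = U (1 + tau_f A) / (1 + U tau_f A)
        x* = 1 / (1 + u* tau_r A)

    Returns ``(u*, x*)``; both lie in (0, 1].  Accepts scalars or arrays.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0.0):
        raise ValueError("presynaptic rate must be non-negative")
    u = stp.U * (1.0 + stp.tau_f * A) / (1.0 + stp.U * stp.tau_f * A)
    x = 1.0 / (1.0 + u * stp.tau_r * A)
    if A.ndim == 0:
        return float(u), float(x)
    return u, x


def steady_state_for_rates(E_r: float, I_r: float,
                           params: StageParameters) -> NetworkState:
    """Lift a point of the rate plane to a full state with STP at steady state."""
    uE, xE = stp_steady_state(E_r, params.E.stp)
    uI, xI = stp_steady_state(I_r, params.I.stp)
    return NetworkState(E_r=float(E_r), I_r=float(I_r),
                        x=np.array([xE, xI, xE, xI]),
                        u=np.array([uE, uI, uE, uI]))


def rest_state(params: StageParameters) -> NetworkState:
    """The quiescent state: zero rates, fully recovered synapses.

    Raises if the origin is not an exact fixed point of the zero-input
    dynamics (which happens when a threshold is zero or negative drive is
    supplied at rest).
    """
    if params.E.theta <= 0.0 or params.I.theta <= 0.0:
        raise ValueError(
            "origin is not a (robust) fixed point: thresholds must be "
            "positive so the quiescent state sits below threshold")
    state = steady_state_for_rates(0.0, 0.0, params)
    dy = rhs_full(0.0, state.as_vector(), params, ZERO_INPUT)
    if np.max(np.abs(dy)) > 1e-12:
        raise ValueError("origin is not a fixed point for these parameters")
    return state


def _active_side(h: float, pop: PopulationParams, override) -> float:
    if override is None:
        return 1.0 if h > pop.theta else 0.0
    return 1.0 if override else 0.0


def jacobian_full(y: np.ndarray, params: StageParameters,
                  ext: ExternalInput = ZERO_INPUT, t: float = 0.0,
                  active_E: bool | None = None,
                  active_I: bool | None = None) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs_full` at a state.

    The transfer function is piecewise linear; off the kink the Jacobian is
    exact.  ``active_E`` / ``active_I`` force the derivative onto the active
    (above-threshold) or silent side, which is how hypothetical operating
    points and kink states are handled by the stability and regime analyses.
    """
    (tauE, tauI, thE, thI, GE, GI, JE, JI,
     UE, trE, tfE, UI, trI, tfI) = _flat(params)
    E, I = y[0], y[1]
    xEE, uEE, xEI, uEI, xIE, uIE, xII, uII = y[2:10]
    hE = JE * uEE * xEE * E - JI * uEI * xEI * I + ext.e_E(t)
    hI = JE * uIE * xIE * E - JI * uII * xII * I + ext.e_I(t)
    sE = GE * _active_side(hE, params.E, active_E)
    sI = GI * _active_side(hI, params.I, active_I)

    J = np.zeros((10, 10))
    J[0, 0] = (-1.0 + sE * JE * uEE * xEE) / tauE
    J[0, 1] = -sE * JI * uEI * xEI / tauE
    J[0, 2] = sE * JE * uEE * E / tauE
    J[0, 3] = sE * JE * xEE * E / tauE
    J[0, 4] = -sE * JI * uEI * I / tauE
    J[0, 5] = -sE * JI * xEI * I / tauE
    J[1, 0] = sI * JE * uIE * xIE / tauI
    J[1, 1] = (-1.0 - sI * JI * uII * xII) / tauI
    J[1, 6] = sI * JE * uIE * E / tauI
    J[1, 7] = sI * JE * xIE * E / tauI
    J[1, 8] = -sI * JI * uII * I / tauI
    J[1, 9] = -sI * JI * xII * I / tauI
    for k, (x, u, A, col, tr, tf, U) in enumerate((
            (xEE, uEE, E, 0, trE, tfE, UE),
            (xEI, uEI, I, 1, trI, tfI, UI),
            (xIE, uIE, E, 0, trE, tfE, UE),
            (xII, uII, I, 1, trI, tfI, UI))):
        rx, ru = 2 + 2 * k, 3 + 2 * k
        J[rx, rx] = -1.0 / tr - u * A
        J[rx, ru] = -x * A
        J[rx, col] = -u * x
        J[ru, ru] = -1.0 / tf - U * A
        J[ru, col] = U * (1.0 - u)
    return J


def jacobian_frozen(r: np.ndarray, params: StageParameters, w: FrozenEfficacies,
                    ext: ExternalInput = ZERO_INPUT, t: float = 0.0,
                    active_E: bool | None = None,
                    active_I: bool | None = None) -> np.ndarray:
    """Analytic 2x2 Jacobian of the frozen-efficacy rate system."""
    wEE, wEI, wIE, wII = w.w
    E, I = r[0], r[1]
    hE = wEE * E - wEI * I + ext.e_E(t)
    hI = wIE * E - wII * I + ext.e_I(t)
    sE = params.E.G * _active_side(hE, params.E, active_E)
    sI = params.I.G * _active_side(hI, params.I, active_I)
    return np.array([
        [(-1.0 + sE * wEE) / params.E.tau, -sE * wEI / params.E.tau],
        [sI * wIE / params.I.tau, (-1.0 - sI * wII) / params.I.tau],
    ])
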