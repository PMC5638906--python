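"""Quasi-nullclines, fixed-point finding and linear stability analysis.

Steady states of the 10D network satisfy a reduced pair of rate equations in
which every STP variable sits at its rate-conditioned steady state
(:func:`stprnn.model.stp_steady_state`).  Fixed points are therefore located
as roots of that reduced 2D system, lifted back to the full state, verified
against the full right-hand side, and classified by the eigenvalues of the
analytic Jacobian of the declared system (10D full, or 2D frozen).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .model import (ExternalInput, FrozenEfficacies, NetworkState,
                    StageParameters, ZERO_INPUT, jacobian_frozen,
                    jacobian_full, rhs_frozen, rhs_full,
                    steady_state_for_rates, stp_steady_state, transfer)

__all__ = [
    "FixedPoint",
    "NullclineCurve",
    "reduced_rhs",
    "quasi_nullclines",
    "find_fixed_points",
    "frozen_fixed_points",
    "classify_stability",
]

MERGE_DISTANCE = 1e-3   # Hz; closer roots are considered the same FP
RESIDUAL_TOL = 1e-8     # max |rhs| at a reported FP
MARGINAL_TOL = 1e-10    # |Re lambda| below this is flagged marginal
KINK_TOL = 1e-9         # |h - theta| below this counts as on the kink


@dataclass(frozen=True)
class FixedPoint:
    """A steady state with its linearization spectrum and verdict."""

    E_r: float
    I_r: float
    system: str                       # "full_10D" or "frozen_2D"
    state: NetworkState | None = None
    eigenvalues: np.ndarray | None = None
    stable: bool | None = None
    flags: tuple[str, ...] = ()

    @property
    def is_origin(self) -> bool:
        return abs(self.E_r) < MERGE_DISTANCE and abs(self.I_r) < MERGE_DISTANCE

    def distance_to(self, other) -> float:
        oE, oI = (other.E_r, other.I_r) if isinstance(other, FixedPoint) else other
        return float(np.hypot(self.E_r - oE, self.I_r - oI))


@dataclass
class NullclineCurve:
    """Sampled points of one quasi-nullcline, split into tagged branches."""

    which: str                        # "E" or "I"
    points: np.ndarray                # (n, 2) array of (E_r, I_r)
    branches: list = field(default_factory=list)  # (tag, slice) pairs


def reduced_rhs(r, params: StageParameters, ext: ExternalInput = ZERO_INPUT,
                t: float = 0.0) -> np.ndarray:
    """Rate derivatives with all STP variables at their steady states."""
    # guard against the root finder's wilder trial points: non-finite or
    # astronomically large rates would otherwise produce non-finite drives
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        return np.where(np.isnan(r) | (r > 0), 1e12, -1e12)
    E = min(max(float(r[0]), 0.0), 1e9)
    I = min(max(float(r[1]), 0.0), 1e9)
    dE_decay = -min(max(r[0], -1e9), 1e9)
    dI_decay = -min(max(r[1], -1e9), 1e9)
    uE, xE = stp_steady_state(E, params.E.stp)
    uI, xI = stp_steady_state(I, params.I.stp)
    P = params.E.J * uE * xE * E
    Q = params.I.J * uI * xI * I
    dE = (dE_decay + transfer(P - Q + ext.e_E(t), params.E)) / params.E.tau
    dI = (dI_decay + transfer(P - Q + ext.e_I(t), params.I)) / params.I.tau
    return np.array([dE, dI])


def _residual(which: str, E: float, I: float, params, ext) -> float:
    """Defining balance of one nullcline, in Hz (rate minus its drive)."""
    d = reduced_rhs((E, I), params, ext)
    tau = params.E.tau if which == "E" else params.I.tau
    return float(d[0] * tau if which == "E" else d[1] * tau)


def _scan_roots(f, grid) -> list[float]:
    """Bracketed roots of a scalar function sampled on a grid."""
    vals = np.array([f(g) for g in grid])
    roots = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0.0:
            roots.append(float(optimize.brentq(f, grid[i], grid[i + 1],
                                               xtol=1e-12)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    return roots


def quasi_nullclines(params: StageParameters,
                     box: tuple[tuple[float, float], tuple[float, float]] =
                     ((0.0, 10.0), (0.0, 10.0)),
                     resolution: int = 201,
                     ext: ExternalInput = ZERO_INPUT
                     ) -> tuple[NullclineCurve, NullclineCurve]:
    """Zero-level curves of the reduced rate equations on a box.

    Only non-negative branches are returned.  Because the transfer function
    clamps at zero, entire segments of the axes can satisfy the balance
    exactly; these are returned as separate ``axis`` branches.
    """
    (E_lo, E_hi), (I_lo, I_hi) = box
    E_grid = np.linspace(E_lo, E_hi, resolution)
    I_grid = np.linspace(I_lo, I_hi, resolution)

    curves = []
    for which in ("E", "I"):
        pts, branches, start = [], [], 0
        # axis branch: the clamped side of the transfer makes the rate's own
        # zero line part of its nullcline wherever the drive is subthreshold
        if which == "E" and E_lo <= 0.0:
            axis_pts = [(0.0, I) for I in I_grid
                        if abs(_residual("E", 0.0, I, params, ext)) < 1e-9]
        elif which == "I" and I_lo <= 0.0:
            axis_pts = [(E, 0.0) for E in E_grid
                        if abs(_residual("I", E, 0.0, params, ext)) < 1e-9]
        else:
            axis_pts = []
        if axis_pts:
            pts.extend(axis_pts)
            branches.append(("axis", slice(start, len(pts))))
            start = len(pts)

        # interior branch: scan along both axes so that near-vertical and
        # near-horizontal stretches of the curve are both captured
        for E in E_grid:
            if E <= 0.0:
                continue
            for I in _scan_roots(
                    lambda I, E=E: _residual(which, E, I, params, ext), I_grid):
                pts.append((E, I))
        for I in I_grid:
            if I <= 0.0 and which == "I":
                continue
            for E in _scan_roots(
                    lambda E, I=I: _residual(which, E, I, params, ext), E_grid):
                if E > 0.0 or which == "I":
                    pts.append((E, I))
        if len(pts) > start:
            branches.append(("interior", slice(start, len(pts))))
        curves.append(NullclineCurve(
            which=which,
            points=np.array(pts).reshape(-1, 2),
            branches=branches))
    return curves[0], curves[1]


def _dedupe(points: list[tuple[float, float]]) -> list[tuple[float, float]]:
    kept: list[tuple[float, float]] = []
    for p in points:
        if not any(np.hypot(p[0] - q[0], p[1] - q[1]) < MERGE_DISTANCE
                   for q in kept):
            kept.append(p)
    return kept


def find_fixed_points(params: StageParameters,
                      search_box: tuple[tuple[float, float], tuple[float, float]] =
                      ((0.0, 10.0), (0.0, 10.0)),
                      n_seeds: int = 25,
                      ext: ExternalInput = ZERO_INPUT) -> list[FixedPoint]:
    """All fixed points of the full network inside a search box.

    Roots of the reduced 2D system are polished from a seed grid (plus the
    origin), deduplicated, lifted to the full 10D state and verified against
    the full right-hand side, then classified by 10D linear stability.
    """
    (E_lo, E_hi), (I_lo, I_hi) = search_box
    seeds = [(0.0, 0.0)]
    for E in np.linspace(E_lo, E_hi, n_seeds):
        for I in np.linspace(I_lo, I_hi, n_seeds):
            seeds.append((float(E), float(I)))

    raw = []
    for seed in seeds:
        sol = optimize.root(lambda r: reduced_rhs(r, params, ext), seed,
                            method="hybr", options={"xtol": 1e-13})
        if not sol.success:
            continue
        E, I = sol.x
        if E < -1e-6 or I < -1e-6:
            continue
        E, I = max(E, 0.0), max(I, 0.0)
        if E > E_hi + 1e-9 or I > I_hi + 1e-9:
            continue
        if np.max(np.abs(reduced_rhs((E, I), params, ext))) > 1e-9:
            continue
        raw.append((E, I))

    out = []
    for (E, I) in sorted(_dedupe(raw)):
        state = steady_state_for_rates(E, I, params)
        residual = np.max(np.abs(rhs_full(0.0, state.as_vector(), params, ext)))
        if residual > RESIDUAL_TOL:
            continue
        fp = FixedPoint(E_r=E, I_r=I, system="full_10D", state=state)
        out.append(classify_stability(fp, params, ext=ext))
    return out


def frozen_fixed_points(params: StageParameters, w: FrozenEfficacies,
                        search_box: tuple[tuple[float, float], tuple[float, float]] =
                        ((0.0, 10.0), (0.0, 10.0)),
                        n_seeds: int = 25,
                        ext: ExternalInput = ZERO_INPUT) -> list[FixedPoint]:
    """Fixed points of the 2D frozen-efficacy system inside a box."""
    (E_lo, E_hi), (I_lo, I_hi) = search_box
    seeds = [(0.0, 0.0)]
    for E in np.linspace(E_lo, E_hi, n_seeds):
        for I in np.linspace(I_lo, I_hi, n_seeds):
            seeds.append((float(E), float(I)))

    def guarded(r):
        r = np.asarray(r, dtype=float)
        if not np.all(np.isfinite(r)) or np.max(np.abs(r)) > 1e9:
            return np.where(np.isnan(r) | (r > 0), 1e12, -1e12)
        return rhs_frozen(0.0, r, params, w, ext)

    raw = []
    for seed in seeds:
        sol = optimize.root(guarded, seed, method="hybr",
                            options={"xtol": 1e-13})
        if not sol.success:
            continue
        E, I = sol.x
        if E < -1e-6 or I < -1e-6:
            continue
        E, I = max(E, 0.0), max(I, 0.0)
        if E > E_hi + 1e-9 or I > I_hi + 1e-9:
            continue
        if np.max(np.abs(rhs_frozen(0.0, np.array([E, I]), params, w, ext))) > 1e-9:
            continue
        raw.append((E, I))

    out = []
    for (E, I) in sorted(_dedupe(raw)):
        fp = FixedPoint(E_r=E, I_r=I, system="frozen_2D")
        out.append(classify_stability(fp, params, system="frozen_2D",
                                      frozen=w, ext=ext))
    return out


def classify_stability(fp: FixedPoint, params: StageParameters,
                       system: str | None = None,
                       frozen: FrozenEfficacies | None = None,
                       ext: ExternalInput = ZERO_INPUT) -> FixedPoint:
    """Fill in the eigenvalue spectrum and the stability verdict of a FP.

    The Jacobian is analytic away from the transfer kink.  A fixed point
    sitting exactly on a kink (net input equal to threshold) is flagged
    ``non_smooth``; the active-side one-sided derivative is used and the
    verdict marked provisional.  Eigenvalues with |Re| <= 1e-10 flag the FP
    ``marginal``.
    """
    system = system or fp.system
    flags: list[str] = []

    if system == "full_10D":
        state = fp.state or steady_state_for_rates(fp.E_r, fp.I_r, params)
        y = state.as_vector()
        hE = (params.E.J * y[3] * y[2] * y[0]
              - params.I.J * y[5] * y[4] * y[1] + ext.e_E(0.0))
        hI = (params.E.J * y[7] * y[6] * y[0]
              - params.I.J * y[9] * y[8] * y[1] + ext.e_I(0.0))
        aE = aI = None
        if abs(hE - params.E.theta) < KINK_TOL:
            flags += ["non_smooth", "provisional"]
            aE = True
        if abs(hI - params.I.theta) < KINK_TOL:
            if "non_smooth" not in flags:
                flags += ["non_smooth", "provisional"]
            aI = True
        J = jacobian_full(y, params, ext=ext, active_E=aE, active_I=aI)
        fp = replace(fp, state=state)
    elif system == "frozen_2D":
        if frozen is None:
            raise ValueError("frozen efficacies are required for a 2D verdict")
        r = np.array([fp.E_r, fp.I_r])
        hE = frozen.w[0] * fp.E_r - frozen.w[1] * fp.I_r + ext.e_E(0.0)
        hI = frozen.w[2] * fp.E_r - frozen.w[3] * fp.I_r + ext.e_I(0.0)
        aE = aI = None
        if abs(hE - params.E.theta) < KINK_TOL:
            flags += ["non_smooth", "provisional"]
            aE = True
        if abs(hI - params.I.theta) < KINK_TOL:
            if "non_smooth" not in flags:
                flags += ["non_smooth", "provisional"]
            aI = True
        J = jacobian_frozen(r, params, frozen, ext=ext, active_E=aE, active_I=aI)
    else:
        raise ValueError(f"unknown system {system!r}")

    eig = np.linalg.eigvals(J)
    max_re = float(eig.real.max())
    stable = max_re < -MARGINAL_TOL
    if abs(max_re) <= MARGINAL_TOL:
        flags.append("marginal")
    return replace(fp, system=system, eigenvalues=eig, stable=stable,
                   flags=tuple(flags))


def fixed_point_report(fps: Sequence[FixedPoint]) -> list[dict]:
    """JSON-ready summary of a list of fixed points."""
    return [{
        "E_r": fp.E_r, "I_r": fp.I_r, "system": fp.system,
        "stable": fp.stable,
        "eigenvalues": [[float(l.real), float(l.imag)]
                        for l in (fp.eigenvalues if fp.eigenvalues is not None
                                  else [])],
        "flags": list(fp.flags),
    } for fp in fps]
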