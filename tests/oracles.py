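"""Independent numerical oracles used to cross-check the implementation."""

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from stprnn import ZERO_INPUT
from stprnn.fixed_points import _residual, quasi_nullclines


def clamped_stp_integration(stp, A, t_end=None, rtol=1e-12, atol=1e-14):
    """(u*, x*) from integrating the STP equations with the rate clamped."""
    if t_end is None:
        t_end = 40.0 * max(stp.tau_r, stp.tau_f)

    def rhs(t, y):
        x, u = y
        return [(1.0 - x) / stp.tau_r - u * x * A,
                (stp.U - u) / stp.tau_f + stp.U * (1.0 - u) * A]

    sol = solve_ivp(rhs, (0.0, t_end), [1.0, stp.U], method="LSODA",
                    rtol=rtol, atol=atol)
    x, u = sol.y[:, -1]
    return float(u), float(x)


def rhs_6d(t, y, params):
    """Reduced formulation with one (x, u) pair per presynaptic population.

    Valid because the STP parameters depend only on the presynaptic side,
    so the EE/IE and EI/II pairs follow identical equations.
    """
    E, I, xE, uE, xI, uI = y
    pe, pi = params.E, params.I
    hE = pe.J * uE * xE * E - pi.J * uI * xI * I
    hI = pe.J * uE * xE * E - pi.J * uI * xI * I
    fE = pe.G * (hE - pe.theta) if hE > pe.theta else 0.0
    fI = pi.G * (hI - pi.theta) if hI > pi.theta else 0.0
    return [
        (-E + fE) / pe.tau,
        (-I + fI) / pi.tau,
        (1.0 - xE) / pe.stp.tau_r - uE * xE * E,
        (pe.stp.U - uE) / pe.stp.tau_f + pe.stp.U * (1.0 - uE) * E,
        (1.0 - xI) / pi.stp.tau_r - uI * xI * I,
        (pi.stp.U - uI) / pi.stp.tau_f + pi.stp.U * (1.0 - uI) * I,
    ]


def finite_difference_jacobian(fun, y, h=1e-6):
    """Central finite differences of a vector field."""
    y = np.asarray(y, dtype=float)
    n = y.size
    f0 = np.asarray(fun(y))
    J = np.empty((f0.size, n))
    for k in range(n):
        yp, ym = y.copy(), y.copy()
        yp[k] += h
        ym[k] -= h
        J[:, k] = (np.asarray(fun(yp)) - np.asarray(fun(ym))) / (2.0 * h)
    return J


def nullcline_intersections(params, box=((0.0, 3.0), (0.0, 3.0)),
                            resolution=301):
    """Intersections of the two quasi-nullclines, found on the curves.

    Walks each sampled curve, evaluates the *other* rate equation's balance
    along it, and refines sign changes by bisection along the connecting
    chord.  Points where both balances already vanish are taken directly.
    This never calls the package's fixed-point finder.
    """
    ncE, ncI = quasi_nullclines(params, box=box, resolution=resolution)
    step = max((box[0][1] - box[0][0]), (box[1][1] - box[1][0])) / (resolution - 1)

    found = []

    def push(pt):
        if not any(np.hypot(pt[0] - q[0], pt[1] - q[1]) < 1e-3 for q in found):
            found.append(pt)

    for curve, other in ((ncE, "I"), (ncI, "E")):
        pts = curve.points
        g = np.array([_residual(other, E, I, params, ZERO_INPUT)
                      for E, I in pts])
        for i, gi in enumerate(g):
            if abs(gi) < 1e-9:
                push(tuple(pts[i]))
        for i in range(len(pts) - 1):
            p, q = pts[i], pts[i + 1]
            if np.hypot(*(q - p)) > 3.0 * step:
                continue
            if g[i] * g[i + 1] < 0.0:
                f = lambda s: _residual(other, *(p + s * (q - p)), params,
                                        ZERO_INPUT)
                s = brentq(f, 0.0, 1.0, xtol=1e-12)
                push(tuple(p + s * (q - p)))
    return found
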