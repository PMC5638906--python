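"""Operating-regime classification and fixed-point-domain maps.

Any point (E_r, I_r) of the rate plane is treated as a potential operating
point: a steady state the network could be placed at by a suitable choice of
thresholds and external drives, with its STP variables at their
rate-conditioned steady states.  Three spectral criteria classify the point:

  A. *Excitatory instability* — with the inhibitory rate clamped at the
     point, the excitatory subsystem (E_r together with the STP variables of
     its recurrent excitatory connection) is linearly unstable.
  B. *Excitatory stability* — the same subsystem is stable on its own.
  C. *Overall stability* — the full linearized network at the point is
     stable, i.e. dynamic feedback inhibition contains whatever instability
     the excitatory side has.

A point satisfying A and C is an inhibition-stabilized network (ISN)
operating point; B and C make it a Non-ISN point; anything else is
unstable.  Because the linearization of a threshold-linear network on its
active side involves neither the thresholds nor the external inputs, the
maps are invariant to theta — raising thresholds moves the actual fixed
points across the map but not the map itself.

Points on the axes are linearized on the silent side of the rectifier for
the silent population (a zero rate at a generic steady state sits below
threshold), which places the quiescent state and the whole E_r = 0 axis in
the Non-ISN domain and the I_r = 0, E_r > 0 branch in the unstable domain
for immature parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .model import StageParameters, jacobian_full, steady_state_for_rates

__all__ = [
    "RegimeLabel",
    "DomainMap",
    "classify_regime_point",
    "fp_domain_map",
    "aod",
    "aod_ratio",
]

MARGINAL_TOL = 1e-10

#: Indices of the excitatory-side subsystem in the 10D state:
#: the E rate plus the (x, u) pair of the recurrent EE connection.
_E_SUBSYSTEM = [0, 2, 3]


class RegimeLabel(Enum):
    ISN = "ISN"
    NON_ISN = "NonISN"
    UNSTABLE = "Unstable"


@dataclass
class DomainMap:
    """Regime labels on a rate-plane lattice anchored at the origin."""

    E_grid: np.ndarray
    I_grid: np.ndarray
    labels: np.ndarray          # (nE, nI) of RegimeLabel values' codes
    stage: str

    _CODES = {RegimeLabel.ISN: 0, RegimeLabel.NON_ISN: 1, RegimeLabel.UNSTABLE: 2}
    _FROM_CODE = {v: k for k, v in _CODES.items()}

    @property
    def box_area(self) -> float:
        return float(self.E_grid[-1] * self.I_grid[-1])

    @property
    def cell_area(self) -> float:
        return self.box_area / self.labels.size

    def label_at(self, iE: int, iI: int) -> RegimeLabel:
        return self._FROM_CODE[int(self.labels[iE, iI])]

    def counts(self) -> dict:
        return {lab: int(np.sum(self.labels == code))
                for lab, code in self._CODES.items()}

    def to_frame(self) -> pd.DataFrame:
        EE, II = np.meshgrid(self.E_grid, self.I_grid, indexing="ij")
        return pd.DataFrame({
            "E_r": EE.ravel(), "I_r": II.ravel(),
            "label": [self._FROM_CODE[c].value for c in self.labels.ravel()],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def classify_regime_point(E_r: float, I_r: float, params: StageParameters,
                          include_stp_in_subsystem: bool = True) -> RegimeLabel:
    """Classify one rate-plane point as ISN, Non-ISN or unstable.

    ``include_stp_in_subsystem=False`` evaluates criterion A on the
    excitatory rate alone (frozen recurrent efficacy), for comparison;
    the default includes the dynamics of the recurrent excitatory synapse,
    whose depression can by itself stabilize the excitatory side.
    """
    if E_r < 0.0 or I_r < 0.0:
        raise ValueError("rates must be non-negative")
    state = steady_state_for_rates(E_r, I_r, params)
    J = jacobian_full(state.as_vector(), params,
                      active_E=E_r > 0.0, active_I=I_r > 0.0)
    idx = _E_SUBSYSTEM if include_stp_in_subsystem else [0]
    sub = J[np.ix_(idx, idx)]
    max_re_sub = float(np.linalg.eigvals(sub).real.max())
    max_re_full = float(np.linalg.eigvals(J).real.max())

    crit_A = max_re_sub > MARGINAL_TOL
    crit_B = max_re_sub < -MARGINAL_TOL
    crit_C = max_re_full < -MARGINAL_TOL
    if crit_A and crit_C:
        return RegimeLabel.ISN
    if crit_B and crit_C:
        return RegimeLabel.NON_ISN
    return RegimeLabel.UNSTABLE


def fp_domain_map(params: StageParameters, E_max: float = 10.0,
                  I_max: float = 10.0, resolution: int = 201,
                  include_stp_in_subsystem: bool = True) -> DomainMap:
    """Dense regime-label lattice on [0, E_max] x [0, I_max]."""
    if E_max <= 0.0 or I_max <= 0.0:
        raise ValueError("box extents must be positive")
    E_grid = np.linspace(0.0, E_max, resolution)
    I_grid = np.linspace(0.0, I_max, resolution)
    labels = np.empty((resolution, resolution), dtype=np.int8)
    for i, E in enumerate(E_grid):
        for j, I in enumerate(I_grid):
            lab = classify_regime_point(E, I, params,
                                        include_stp_in_subsystem)
            labels[i, j] = DomainMap._CODES[lab]
    return DomainMap(E_grid=E_grid, I_grid=I_grid, labels=labels,
                     stage=params.stage)


def aod(domain_map: DomainMap, label: RegimeLabel) -> float:
    """Area of one regime's domain (Hz^2), cell-count times cell-area."""
    code = DomainMap._CODES[label]
    return float(np.sum(domain_map.labels == code)) * domain_map.cell_area


def aod_ratio(params: StageParameters | None = None, E_max: float = 10.0,
              I_max: float = 10.0, resolution: int = 201,
              domain_map: DomainMap | None = None) -> float:
    """Ratio of the ISN domain area to the unstable domain area.

    Computes the domain map from ``params`` unless one is supplied.
    Returns ``inf`` when the unstable domain has vanished from the box.
    """
    if domain_map is None:
        if params is None:
            raise ValueError("either params or a precomputed map is required")
        domain_map = fp_domain_map(params, E_max, I_max, resolution)
    unstable = aod(domain_map, RegimeLabel.UNSTABLE)
    isn = aod(domain_map, RegimeLabel.ISN)
    if unstable == 0.0:
        return math.inf
    return isn / unstable
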