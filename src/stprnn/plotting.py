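"""Optional plotting helpers (never load-bearing for any analysis)."""

from __future__ import annotations

import numpy as np

from .regimes import DomainMap, RegimeLabel
from .simulate import Trajectory

_COLORS = {RegimeLabel.ISN: "#f7e7a9", RegimeLabel.NON_ISN: "#f2c4c4",
           RegimeLabel.UNSTABLE: "#f0d000"}


def plot_trajectory(traj: Trajectory, ax=None, n: int = 2001):
    """Population rates and the summed activity against time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t, y = traj.sample(n)
    ax.plot(t, y[0], label="E_r", color="tab:red")
    ax.plot(t, y[1], label="I_r", color="tab:blue")
    ax.plot(t, y[0] + y[1], label="A_sum", color="k", lw=0.8, ls="--")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("rate (Hz)")
    ax.legend(frameon=False)
    return ax


def plot_domain_map(dmap: DomainMap, ax=None):
    """Colour-coded operating-regime domains in the rate plane."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if ax is None:
        _, ax = plt.subplots()
    cmap = ListedColormap([_COLORS[RegimeLabel.ISN],
                           _COLORS[RegimeLabel.NON_ISN],
                           _COLORS[RegimeLabel.UNSTABLE]])
    ax.pcolormesh(dmap.E_grid, dmap.I_grid, dmap.labels.T, cmap=cmap,
                  vmin=-0.5, vmax=2.5, shading="nearest")
    ax.set_xlabel("E_r (Hz)")
    ax.set_ylabel("I_r (Hz)")
    ax.set_title(f"{dmap.stage}: ISN / Non-ISN / unstable domains")
    return ax
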