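"""Developmental stage registry and parameter-substitution experiments.

The four modelled stages — P3, P10, P14 and P20 — bracket eye-opening in the
rodent visual cortex.  Their parameter values (shipped in
``data/stages.json``) encode the experimentally reported maturation of
membrane/synaptic kinetics (tau_E, tau_I), short-term plasticity (U, tau_r,
tau_f), absolute synaptic efficacies (J_E, J_I) and activity thresholds
(theta_E, theta_I).

Substitution experiments replace a named subset of a base stage's parameters
by a donor stage's values and re-measure the burst-size and operating-regime
metrics; the ``ratio`` metrics express the induced change as a percentage of
the full base-to-donor developmental change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .model import (PopulationParams, PresynapticSTPParams, StageParameters)

__all__ = [
    "STAGE_LABELS",
    "PARAMETER_NAMES",
    "PARAMETER_GROUPS",
    "SubstitutionSpec",
    "RatioResult",
    "load_stage",
    "stage_table",
    "substitute",
    "ratio_metric",
    "run_substitution_experiment",
]

STAGE_LABELS: tuple[str, ...] = ("P3", "P10", "P14", "P20")

#: Canonical flat parameter names, as they appear in the packaged registry.
PARAMETER_NAMES: tuple[str, ...] = (
    "tau_E", "tau_I", "tau_rE", "tau_rI", "tau_fE", "tau_fI",
    "U_E", "U_I", "J_E", "J_I", "theta_E", "theta_I",
)

#: Named parameter combinations used by the substitution experiments.
PARAMETER_GROUPS: dict[str, tuple[str, ...]] = {
    "J": ("J_E", "J_I"),
    "tau_syn": ("tau_E", "tau_I"),
    "STP_E": ("U_E", "tau_rE", "tau_fE"),
    "STP_I": ("U_I", "tau_rI", "tau_fI"),
    "STP_all": ("U_E", "tau_rE", "tau_fE", "U_I", "tau_rI", "tau_fI"),
    "theta": ("theta_E", "theta_I"),
    "all": PARAMETER_NAMES,
}


@lru_cache(maxsize=1)
def _registry() -> dict:
    with resources.files("stprnn.data").joinpath("stages.json").open() as fh:
        raw = json.load(fh)
    return {k: v for k, v in raw.items() if not k.startswith("_")}


def _from_flat(flat: dict, stage: str) -> StageParameters:
    return StageParameters(
        stage=stage,
        E=PopulationParams(
            tau=flat["tau_E"], theta=flat["theta_E"], J=flat["J_E"],
            stp=PresynapticSTPParams(U=flat["U_E"], tau_r=flat["tau_rE"],
                                     tau_f=flat["tau_fE"])),
        I=PopulationParams(
            tau=flat["tau_I"], theta=flat["theta_I"], J=flat["J_I"],
            stp=PresynapticSTPParams(U=flat["U_I"], tau_r=flat["tau_rI"],
                                     tau_f=flat["tau_fI"])),
    )


def _to_flat(params: StageParameters) -> dict:
    E, I = params.E, params.I
    return {
        "tau_E": E.tau, "tau_I": I.tau,
        "tau_rE": E.stp.tau_r, "tau_rI": I.stp.tau_r,
        "tau_fE": E.stp.tau_f, "tau_fI": I.stp.tau_f,
        "U_E": E.stp.U, "U_I": I.stp.U,
        "J_E": E.J, "J_I": I.J,
        "theta_E": E.theta, "theta_I": I.theta,
    }


def load_stage(label: str) -> StageParameters:
    """Load the registry parameter set for one postnatal stage."""
    reg = _registry()
    if label not in reg:
        raise ValueError(
            f"unknown stage {label!r}; valid stages are {', '.join(reg)}")
    return _from_flat(reg[label], label)


def stage_table() -> pd.DataFrame:
    """The full stage registry as a parameters-by-stages DataFrame."""
    reg = _registry()
    return pd.DataFrame({s: reg[s] for s in STAGE_LABELS}).loc[list(PARAMETER_NAMES)]


@dataclass(frozen=True)
class SubstitutionSpec:
    """Replace named parameters of ``base_stage`` by ``donor_stage`` values."""

    base_stage: str
    donor_stage: str
    parameters: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if self.base_stage == self.donor_stage:
            raise ValueError("base and donor stage must differ")
        bad = [p for p in self.parameters if p not in PARAMETER_NAMES]
        if bad:
            raise ValueError(f"unknown parameter names: {bad}")
        if not self.parameters:
            raise ValueError("at least one parameter must be named")
        if not self.name:
            object.__setattr__(self, "name", "+".join(self.parameters))

    @classmethod
    def from_group(cls, base_stage: str, donor_stage: str,
                   group: str) -> "SubstitutionSpec":
        if group not in PARAMETER_GROUPS:
            raise ValueError(
                f"unknown group {group!r}; valid groups: {list(PARAMETER_GROUPS)}")
        return cls(base_stage, donor_stage, PARAMETER_GROUPS[group], name=group)


def substitute(spec: SubstitutionSpec) -> StageParameters:
    """Build the hybrid parameter set described by a substitution spec."""
    flat = dict(_to_flat(load_stage(spec.base_stage)))
    donor = _to_flat(load_stage(spec.donor_stage))
    for p in spec.parameters:
        flat[p] = donor[p]
    return _from_flat(flat, "custom")


@dataclass(frozen=True)
class RatioResult:
    """One substitution outcome for one metric, as percent of the full change."""

    gamma_name: str
    gamma_base: float
    gamma_donor: float
    gamma_res: float
    ratio: float  # percent


def ratio_metric(gamma_res: float, gamma_base: float, gamma_donor: float,
                 sign: int) -> float:
    """Substitution-induced change as a percentage of the developmental change.

    ``100 * sign * (gamma_res - gamma_base) / (gamma_donor - gamma_base)``.
    ``sign`` is -1 for metrics that normally decrease across the transition
    (burst size) and +1 for metrics that increase (ISN/unstable area ratio),
    so that the full developmental change maps to -100% and +100%
    respectively.
    """
    if sign not in (-1, 1):
        raise ValueError("sign must be -1 or +1")
    denom = gamma_donor - gamma_base
    if denom == 0.0:
        raise ZeroDivisionError(
            "metric does not change between base and donor stage")
    return 100.0 * sign * (gamma_res - gamma_base) / denom


def default_specs(base: str = "P10", donor: str = "P20") -> list[SubstitutionSpec]:
    """All single parameters plus the named combinations."""
    specs = [SubstitutionSpec(base, donor, (p,)) for p in PARAMETER_NAMES]
    specs += [SubstitutionSpec.from_group(base, donor, g)
              for g in ("J", "tau_syn", "STP_E", "STP_I", "STP_all", "theta", "all")]
    return specs


def run_substitution_experiment(
        base: str = "P10", donor: str = "P20",
        specs: Sequence[SubstitutionSpec] | None = None,
        amplitude: float = 30.0, width: float = 1e-3,
        map_resolution: int = 201,
        box: tuple[float, float] = (10.0, 10.0)) -> pd.DataFrame:
    """Measure ratio_PS and ratio_AOD for a list of substitutions.

    For each spec the burst size PS_net_amp is measured under the standard
    impulse protocol (``amplitude`` Hz external pulse of ``width`` s to the E
    population from rest) and the ISN/unstable area ratio on the
    ``box``-sized rate plane; both are expressed relative to the full
    base-to-donor developmental change via :func:`ratio_metric`.
    """
    from .clusters import ps_net_amp
    from .regimes import aod_ratio
    from .simulate import run_impulse_protocol

    if specs is None:
        specs = default_specs(base, donor)

    def gamma_ps(params: StageParameters) -> float:
        traj = run_impulse_protocol(params, amplitude=amplitude, width=width)
        return ps_net_amp(traj)

    def gamma_aod(params: StageParameters) -> float:
        return aod_ratio(params, E_max=box[0], I_max=box[1],
                         resolution=map_resolution)

    p_base, p_donor = load_stage(base), load_stage(donor)
    ps_base, ps_donor = gamma_ps(p_base), gamma_ps(p_donor)
    aod_base, aod_donor = gamma_aod(p_base), gamma_aod(p_donor)

    rows = []
    for spec in specs:
        if spec.base_stage != base or spec.donor_stage != donor:
            raise ValueError("spec stages must match the experiment stages")
        hybrid = substitute(spec)
        ps_res = gamma_ps(hybrid)
        aod_res = gamma_aod(hybrid)
        rows.append({
            "spec": spec.name,
            "parameters": ",".join(spec.parameters),
            "ps_res": ps_res,
            "aod_res": aod_res,
            "ratio_PS": ratio_metric(ps_res, ps_base, ps_donor, sign=-1),
            "ratio_AOD": ratio_metric(aod_res, aod_base, aod_donor, sign=+1),
        })
    out = pd.DataFrame(rows)
    out.attrs.update(ps_base=ps_base, ps_donor=ps_donor,
                     aod_base=aod_base, aod_donor=aod_donor)
    return out
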