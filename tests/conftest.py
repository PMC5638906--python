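import numpy as np
import pytest
from hypothesis import settings

import stprnn as sp

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

STAGES = sp.STAGE_LABELS


@pytest.fixture(scope="session")
def stages():
    return {s: sp.load_stage(s) for s in STAGES}


@pytest.fixture(scope="session")
def impulse_trajs(stages):
    """Standard 30 Hz / 1 ms impulse-protocol trajectories, intact."""
    return {s: sp.run_impulse_protocol(p) for s, p in stages.items()}


@pytest.fixture(scope="session")
def gaba_trajs(stages):
    """Impulse-protocol trajectories with the inhibitory efficacy blocked."""
    spec = sp.BlockadeSpec(target="GABAergic")
    return {s: sp.run_impulse_protocol(sp.apply_blockade(p, spec))
            for s, p in stages.items()}


@pytest.fixture(scope="session")
def stage_fps(stages):
    return {s: sp.find_fixed_points(p) for s, p in stages.items()}


@pytest.fixture(scope="session")
def domain_maps(stages):
    return {s: sp.fp_domain_map(p, resolution=101)
            for s, p in stages.items()}
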