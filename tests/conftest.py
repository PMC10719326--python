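import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from memanchor import (  # noqa: E402
    MembraneComposition,
    SyntheticParams,
    build_system,
    simulate_adsorption,
)


@pytest.fixture(scope="session")
def small_params():
    """Short adsorption run used by several metric tests."""
    return SyntheticParams(n_steps=20_000, write_stride=50, seed=42)


@pytest.fixture(scope="session")
def small_run(small_params):
    topo, frame0, bead = build_system(small_params)
    traj = simulate_adsorption(small_params, topo, frame0)
    return topo, traj, bead
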