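import numpy as np
import pytest

from herdsim import Arena
from herdsim.fixtures import sample_initial_conditions
from herdsim.simulator import run_trial


@pytest.fixture(scope="session")
def arena():
    return Arena()


@pytest.fixture(scope="session")
def single_ta_log():
    """One completed single-target rollout shared across tests."""
    for cfg in sample_initial_conditions(10, seed=42):
        log = run_trial(cfg)
        if log.completed:
            return log
    raise RuntimeError("no completing rollout in the fixture sample")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240815)
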