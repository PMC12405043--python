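import numpy as np
import pytest

from neuropinch import force as force_mod
from neuropinch.synthetic import (CommonDriveSpec, ProtocolSpec, generate_pool,
                                  simulate_trial)


@pytest.fixture(scope="session")
def protocol():
    return ProtocolSpec()


@pytest.fixture(scope="session")
def small_pools():
    """Compact 12-unit pools, enough for fast end-to-end checks."""
    return {"APB": generate_pool(12, seed=0), "FDS": generate_pool(12, seed=1)}


@pytest.fixture(scope="session")
def trial35(protocol, small_pools):
    """One mid-force trial with no shared drive."""
    return simulate_trial(small_pools, CommonDriveSpec(strength=0.0),
                          protocol, 0.35, seed=3)


@pytest.fixture(scope="session")
def steady_window(trial35):
    return force_mod.find_steadiest_window(trial35.force_trace())


@pytest.fixture
def rng():
    return np.random.default_rng(0)
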