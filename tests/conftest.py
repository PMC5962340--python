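import numpy as np
import pytest

from charkit.bridge import BridgeSpec
from charkit.simulate import DEFAULT_BRIDGE_SEQUENCE, SimConfig, simulate_dataset


@pytest.fixture
def bridge_spec():
    return BridgeSpec(sequence=DEFAULT_BRIDGE_SEQUENCE, max_mismatches=1, min_flank=15)


@pytest.fixture
def exact_bridge_spec():
    return BridgeSpec(sequence=DEFAULT_BRIDGE_SEQUENCE, max_mismatches=0, min_flank=15)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def small_simdata():
    """A modest zero-noise dataset shared by read-level tests."""
    config = SimConfig(seed=42, n_reads=3000)
    return simulate_dataset(config)
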