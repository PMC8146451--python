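import numpy as np
import pytest

from introbsa import synthetic_data as sd


@pytest.fixture(scope="session")
def demo_experiment():
    """One default 9-lineage introgression experiment, shared across tests."""
    return sd.simulate_bulk_experiment(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
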