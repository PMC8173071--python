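import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from isoscribe.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The standard desk-scale simulation (seed 1), shared across tests."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def clean_dataset():
    """No jitter, no truncation, no noise — structures are exact."""
    cfg = SimulationConfig(
        seed=5,
        jitter_sd=0.0,
        truncation_prob=0.0,
        noise_read_rate=0.0,
        n_genes=10,
    )
    return simulate_dataset(cfg)
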