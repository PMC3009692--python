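import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from colligator.sequence_io import Read
from colligator.synthetic_data import SimulationConfig, SyntheticDataset, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset() -> SyntheticDataset:
    """One default-configuration synthetic dataset shared across tests."""
    return simulate_dataset(SimulationConfig(rng_seed=17))


@pytest.fixture(scope="session")
def default_reads(default_dataset) -> list[Read]:
    return [Read(i, s) for i, s in default_dataset.reads]
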