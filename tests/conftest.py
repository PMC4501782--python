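import numpy as np
import pytest

from altiscan import SelectedLocus, SimulationConfig, simulate_scan_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Two short scaffolds, one selected locus, complete genotypes."""
    cfg = SimulationConfig(
        n_scaffolds=2,
        scaffold_length=100_000,
        selected=[SelectedLocus(0, 50_000)],
        seed=42,
    )
    return simulate_scan_dataset(cfg)


@pytest.fixture(scope="session")
def neutral_dataset():
    """Four short scaffolds, no selection."""
    cfg = SimulationConfig(
        n_scaffolds=4, scaffold_length=50_000, selected=[], seed=7
    )
    return simulate_scan_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
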