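import numpy as np
import pytest

from wgdkit.simulate import SimulationConfig, simulate_wgd_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-gene simulated dataset shared by synteny/pipeline tests."""
    cfg = SimulationConfig(seed=7, n_ancestral_genes=300)
    return simulate_wgd_dataset(cfg)


@pytest.fixture(scope="session")
def full_retention_dataset():
    """No losses, no tandems: every outgroup gene keeps both duplicates."""
    cfg = SimulationConfig(
        seed=3,
        n_ancestral_genes=200,
        retention_prob={"drought_up": 1.0, "background": 1.0},
        tandem_rate=0.0,
        decoy_hit_rate=0.0,
    )
    return simulate_wgd_dataset(cfg)
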