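import numpy as np
import pytest

from snpset.simulate import SimConfig, simulate_replicate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_replicate():
    """A small analysis-ready synthetic cohort shared across tests."""
    cfg = SimConfig(n_samples=250, n_genes=8, mean_variants_per_gene=8)
    return simulate_replicate(cfg, seed=99)
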