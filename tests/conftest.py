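import numpy as np
import pytest

from cernaforge import synthetic as syn


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic experiment bundle, shared across tests."""
    return syn.generate_bundle(syn.SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down configuration for fast end-to-end checks."""
    return syn.SimConfig(
        seed=7,
        n_features={"mRNA": 120, "lncRNA": 40, "circRNA": 40, "miRNA": 12},
        n_triads=4,
        background_nodes=10,
        gene_set_size_range=(20, 40),
        n_gene_sets=8,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return syn.generate_bundle(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
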