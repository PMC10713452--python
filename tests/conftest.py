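import numpy as np
import pytest

from isocover.synth import SynthConfig, generate_dataset, generate_gene_models


@pytest.fixture(scope="session")
def small_dataset():
    """A compact seeded bundle shared by read-only tests."""
    cfg = SynthConfig(n_genes=10, seed=42)
    result, tables = generate_dataset(cfg)
    return result, tables


@pytest.fixture(scope="session")
def cassette_result():
    cfg = SynthConfig(n_genes=12, cassette_fraction=1.0, seed=7)
    return generate_gene_models(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
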