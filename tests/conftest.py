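import numpy as np
import pytest

from perturbsig import GeneratorConfig, collapse_dataset, generate_signature_dataset


@pytest.fixture(scope="session")
def default_shrna():
    """Default shRNA study conditions: 50 landmark-targeted genes x 6
    reagents x 3 cell lines x 3 replicates, seed effect > gene effect."""
    return generate_signature_dataset(GeneratorConfig(rng_seed=20))


@pytest.fixture(scope="session")
def default_shrna_collapsed(default_shrna):
    dataset, truth = default_shrna
    return collapse_dataset(dataset), truth


@pytest.fixture(scope="session")
def small_shrna():
    """Small dataset for cheap structural tests."""
    cfg = GeneratorConfig(n_genes_targeted=10, n_cell_lines=2, rng_seed=7)
    return generate_signature_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
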