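import numpy as np
import pytest

from bsamap import default_trait_model, simulate_parental_genomes


@pytest.fixture(scope="session")
def small_map():
    """Compact 4-chromosome map for fast unit tests."""
    return simulate_parental_genomes(4, 40, 400_000, 1.0, seed=11)


@pytest.fixture(scope="session")
def yeast_map():
    """Study-scale map: 16 chromosomes x 350 markers (5,600 informative
    SNPs), 750 kb and 2.7 Morgans per chromosome."""
    return simulate_parental_genomes(16, 350, 750_000, 2.7, seed=7)


@pytest.fixture(scope="session")
def yeast_model(yeast_map):
    return default_trait_model(yeast_map)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
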