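import numpy as np
import pytest

from qpss import GenotypeMatrix, Region, simulate_haplotypes


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_pool():
    """A 100 kb mini-region pool shared across tests."""
    return simulate_haplotypes(
        n_hap=2000, region_length=100_000, variant_density=5e-3, sfs_alpha=1.0,
        seed=42,
    )


@pytest.fixture
def toy_genotypes():
    """Ten variants, eight samples, hand-laid dosages (no missing)."""
    dosages = np.zeros((8, 10), dtype=np.int8)
    # samples 0-5 are carriers at various positions; 6-7 carry nothing
    dosages[0, 0] = 1
    dosages[1, 1] = 1
    dosages[2, 3] = 2
    dosages[3, 5] = 1
    dosages[4, 6] = 1
    dosages[4, 7] = 1
    dosages[5, 9] = 1
    positions = np.arange(100, 1100, 100)  # 100..1000
    ids = np.array([f"s{i}" for i in range(8)])
    return GenotypeMatrix(ids, positions, dosages)


@pytest.fixture
def toy_region():
    return Region("1", 1, 1000)
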