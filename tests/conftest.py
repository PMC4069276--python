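import numpy as np
import pytest

import halfsib as hs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hand_family():
    """3-sib worked family: sire strands 00000/11111, one recombination in C."""
    g = np.array(
        [
            [0, 0, 0, 0, 0],  # A inherits strand 1, dam alleles 0
            [2, 2, 2, 2, 2],  # B inherits strand 2, dam alleles 1
            [0, 0, 2, 2, 2],  # C switches strands between SNP 2 and 3
        ],
        dtype=np.int8,
    )
    return hs.GenotypeMatrix(["A", "B", "C"], g)


@pytest.fixture
def small_sim():
    return hs.simulate_population(
        hs.SimConfig(n_families=1, family_sizes=8, n_snps=500, seed=7)
    )


def random_genotypes(rng, n, m, missing_rate=0.1):
    v = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    v[rng.random((n, m)) < missing_rate] = 9
    return hs.GenotypeMatrix([f"i{k}" for k in range(n)], v)
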