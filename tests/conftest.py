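import numpy as np
import pytest

from craterdemog.types import GenotypeTable, Locus


@pytest.fixture
def two_pop_snp_table():
    """8 individuals (4 + 4), 3 biallelic SNPs with known genotype counts."""
    rng = np.random.default_rng(42)
    calls = rng.integers(0, 2, size=(8, 3, 2)).astype(np.int32)
    loci = [Locus(id=f"s{j}", tag=f"tag{j}", position=10) for j in range(3)]
    return GenotypeTable(
        [f"ind{i}" for i in range(8)],
        loci,
        calls,
        populations=["p1"] * 4 + ["p2"] * 4,
    )


@pytest.fixture
def fixed_difference_table():
    """Two populations fixed for different alleles at every locus."""
    calls = np.zeros((8, 3, 2), dtype=np.int32)
    calls[4:, :, :] = 1
    loci = [Locus(id=f"s{j}") for j in range(3)]
    return GenotypeTable(
        [f"ind{i}" for i in range(8)],
        loci,
        calls,
        populations=["p1"] * 4 + ["p2"] * 4,
    )
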