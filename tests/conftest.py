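import numpy as np
import pytest

from kinpods import AlleleFrequencyTable, MultilocusGenotype

LOCI8 = tuple(f"L{i}" for i in range(1, 9))


@pytest.fixture(scope="session")
def freqs8x10():
    """The default informative panel: 8 loci, 10 equifrequent alleles."""
    return AlleleFrequencyTable.equifrequent(LOCI8, 10)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_genotype(pairs, loci=None):
    """Shorthand genotype builder; ``pairs`` is a list of (a, b) or None."""
    loci = tuple(loci) if loci is not None else tuple(f"L{i}" for i in range(1, len(pairs) + 1))
    return MultilocusGenotype(loci, tuple(pairs))


@pytest.fixture
def geno():
    return make_genotype
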