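import numpy as np
import pytest

from sirescue.genetics import DiploidGenotype
from sirescue.landscape import Landscape


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_genotype(s1, s2, neutral=None):
    """Genotype with given S alleles and homozygous-1 neutral loci by default."""
    if neutral is None:
        neutral = tuple((1, 1) for _ in range(5))
    return DiploidGenotype(s=(s1, s2), neutral=neutral)


@pytest.fixture
def open_landscape():
    """Fully suitable 30x30 grid."""
    return Landscape(np.ones((30, 30), dtype=bool))


def all_het_genotypes(k):
    """All S-heterozygous genotypes over ranks 1..k."""
    return [make_genotype(a, b) for a in range(1, k + 1) for b in range(a + 1, k + 1)]


def all_genotypes(k):
    """All S genotypes (incl. homozygotes) over ranks 1..k."""
    return [make_genotype(a, b) for a in range(1, k + 1) for b in range(a, k + 1)]
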