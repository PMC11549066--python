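"""S-locus genetics for sporophytic self-incompatibility (SSI).

S alleles are positive integer ranks forming a strict linear dominance
hierarchy on the pollen side: rank 1 dominates rank 2, which dominates
rank 3, and so on, open-ended so that rescue interventions can mint
ranks beyond those segregating in a population.  A pollen grain's
incompatibility phenotype is determined sporophytically, i.e. by the
diploid genotype of the donor plant: only the dominant (lowest-rank)
allele of the donor is expressed.  The pistil is codominant by default
(it rejects pollen whose phenotype matches either of its own alleles);
a pistil-dominant variant is available through ``pistil_model``.

Besides the S locus, each genotype carries five unlinked neutral diploid
loci (three alleles each at initialisation) used for the fixation index
F_IS and for tracking immigrant ancestry.

Scalar operations work on :class:`DiploidGenotype`; the simulation
engine uses the ``*_arr`` vectorised counterparts on integer arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

N_NEUTRAL_LOCI = 5
N_NEUTRAL_ALLELES = 3  # founder allele ids per neutral locus: {1, 2, 3}

__all__ = [
    "N_NEUTRAL_LOCI",
    "N_NEUTRAL_ALLELES",
    "DiploidGenotype",
    "HaploidGamete",
    "pollen_phenotype",
    "pistil_rejects",
    "is_compatible",
    "sample_gamete",
    "fuse",
    "count_s_alleles",
    "fixation_index",
    "pollen_phenotype_arr",
    "compatible_arr",
    "count_s_alleles_arr",
    "fixation_index_arr",
]


@dataclass(frozen=True)
class DiploidGenotype:
    """Two S-locus alleles plus five neutral diploid loci.

    ``s`` is an unordered pair of S-allele ranks (>= 1); ``neutral`` is a
    tuple of five unordered allele-id pairs.  Founders are S-heterozygous
    by construction; offspring may be S-homozygous (reachable under
    paternal dominance when the donor's expressed allele differs from
    the transmitted one).
    """

    s: tuple[int, int]
    neutral: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.s) != 2 or min(self.s) < 1:
            raise ValueError(f"genotype needs two S alleles with rank >= 1, got {self.s}")
        if len(self.neutral) != N_NEUTRAL_LOCI:
            raise ValueError(f"expected {N_NEUTRAL_LOCI} neutral loci, got {len(self.neutral)}")


@dataclass(frozen=True)
class HaploidGamete:
    """One S allele and one allele per neutral locus, all drawn from a parent."""

    s: int
    neutral: tuple[int, ...]


def pollen_phenotype(donor: DiploidGenotype) -> int:
    """Expressed S specificity of the donor's pollen: its dominant (min-rank) allele."""
    return min(donor.s)


def pistil_rejects(pistil: DiploidGenotype, phenotype: int, pistil_model: str = "codominant") -> bool:
    """Whether a pistil rejects pollen of the given S phenotype.

    Codominant pistils (default) reject a phenotype matching either of
    their alleles; dominant pistils express only their dominant allele.
    """
    if pistil_model == "codominant":
        return phenotype in pistil.s
    if pistil_model == "dominant":
        return phenotype == min(pistil.s)
    raise ValueError(f"unknown pistil_model {pistil_model!r}")


def is_compatible(donor: DiploidGenotype, pistil: DiploidGenotype, pistil_model: str = "codominant") -> bool:
    """True iff the donor's pollen phenotype is accepted by the pistil.

    Compatibility may be asymmetric: a cross can succeed in one
    direction and fail in the other, because only the donor's dominant
    allele is screened against the pistil.
    """
    return not pistil_rejects(pistil, pollen_phenotype(donor), pistil_model)


def sample_gamete(parent: DiploidGenotype, rng: np.random.Generator) -> HaploidGamete:
    """Mendelian gamete: one allele per locus, fair coin, loci independent (unlinked)."""
    picks = rng.integers(0, 2, size=1 + N_NEUTRAL_LOCI)
    return HaploidGamete(
        s=parent.s[picks[0]],
        neutral=tuple(parent.neutral[i][picks[1 + i]] for i in range(N_NEUTRAL_LOCI)),
    )


def fuse(ovule: HaploidGamete, pollen: HaploidGamete) -> DiploidGenotype:
    """Union of two gametes into an offspring genotype (no mutation)."""
    return DiploidGenotype(
        s=(ovule.s, pollen.s),
        neutral=tuple((ovule.neutral[i], pollen.neutral[i]) for i in range(N_NEUTRAL_LOCI)),
    )


def count_s_alleles(genotypes: Iterable[DiploidGenotype]) -> int:
    """Number of distinct S-allele ranks present; 0 for an empty collection."""
    ranks: set[int] = set()
    for g in genotypes:
        ranks.update(g.s)
    return len(ranks)


def fixation_index(genotypes: Sequence[DiploidGenotype]) -> float:
    """F_IS = 1 - H_o/H_e averaged over polymorphic neutral loci; NaN if undefined."""
    if len(genotypes) < 2:
        return float("nan")
    neutral = np.array([g.neutral for g in genotypes], dtype=np.int64)
    return fixation_index_arr(neutral)


# ---------------------------------------------------------------------------
# vectorised counterparts used by the simulation engine


def pollen_phenotype_arr(s_pairs: np.ndarray) -> np.ndarray:
    """Dominant (min-rank) allele per row of an (n, 2) S-genotype array."""
    return s_pairs.min(axis=1)


def compatible_arr(
    donor_phenotype: np.ndarray,
    pistil_s: np.ndarray,
    pistil_model: str = "codominant",
) -> np.ndarray:
    """Elementwise compatibility of donor phenotypes against pistil genotypes.

    ``donor_phenotype`` has shape (k,), ``pistil_s`` shape (k, 2); both are
    aligned per cross.  Returns a boolean array of shape (k,).
    """
    if pistil_model == "codominant":
        return (donor_phenotype != pistil_s[:, 0]) & (donor_phenotype != pistil_s[:, 1])
    if pistil_model == "dominant":
        return donor_phenotype != pistil_s.min(axis=1)
    raise ValueError(f"unknown pistil_model {pistil_model!r}")


def count_s_alleles_arr(s_pairs: np.ndarray) -> int:
    if s_pairs.size == 0:
        return 0
    return int(np.unique(s_pairs).size)


def fixation_index_arr(neutral: np.ndarray) -> float:
    """F_IS over an (n, loci, 2) neutral-genotype array.

    Per locus: H_o is the observed heterozygote fraction and
    H_e = 1 - sum(p_i^2) the Hardy-Weinberg expected heterozygosity from
    the sample allele frequencies; loci with H_e = 0 (monomorphic) carry
    no information and are dropped.  Returns NaN when fewer than two
    individuals or no polymorphic locus remains, so that monomorphic
    collapse is visible in outputs rather than silently reported as 0.
    """
    n = neutral.shape[0]
    if n < 2:
        return float("nan")
    values = []
    for locus in range(neutral.shape[1]):
        a = neutral[:, locus, 0]
        b = neutral[:, locus, 1]
        h_o = float(np.mean(a != b))
        alleles, counts = np.unique(np.concatenate([a, b]), return_counts=True)
        p = counts / counts.sum()
        h_e = 1.0 - float(np.sum(p**2))
        if h_e > 0.0:
            values.append(1.0 - h_o / h_e)
    if not values:
        return float("nan")
    return float(np.mean(values))
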