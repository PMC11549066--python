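"""Rescue interventions: demographic, genetic, and habitat.

All three fire from the same trigger — the count of reproductive
plants dropping below a threshold (default 50), checked once per year
before reproduction — and by default fire once per simulation run.

* **Demographic rescue** introduces ``n`` locally sourced seedlings:
  every locus of every seedling is drawn from the threatened
  population's own allele frequencies, so locally common alleles are
  the most likely to be represented and S-allele richness never
  increases.
* **Genetic rescue** introduces ``n`` seedlings of which each is,
  independently with probability ``p_s``, an immigrant carrying S
  alleles (and neutral alleles) absent from the threatened population;
  with probability ``1 - p_s`` it is a locally sourced seedling, so
  ``p_s = 0`` reduces exactly to demographic rescue.
* **Habitat rescue** raises the suitable-site fraction of the lattice
  to ``phi_new`` without touching the population.

Immigrant alleles are minted from the open-ended rank series beyond
any rank the population has ever carried; being the highest ranks they
are recessive to all resident alleles, and an immigrant's expressed
pollen phenotype is therefore compatible with every resident pistil.
Each rescue event mints one common immigrant source pool (as many S
alleles as the founder population had, three novel ids per neutral
locus) from which its immigrants draw, mimicking sourcing from a
single external population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genetics import N_NEUTRAL_LOCI
from .landscape import upgrade_suitability
from .lifecycle import Population, SimState

__all__ = [
    "RescuePlan",
    "check_trigger",
    "demographic_rescue",
    "genetic_rescue",
    "habitat_rescue",
    "apply_plan",
]

VALID_KINDS = frozenset({"demographic", "genetic", "habitat"})


@dataclass(frozen=True)
class RescuePlan:
    """Which intervention(s) fire when the reproductive count drops below the trigger."""

    kinds: frozenset = field(default_factory=frozenset)
    n_introduced: int = 0
    p_s: float = 0.0
    phi_new: Optional[float] = None
    trigger_threshold: int = 50
    fire_once: bool = True
    novel_alleles: str = "both"  # immigrants carry both S alleles novel, or just "one"
    habitat_mode: str = "absolute"  # phi_new as target fraction, or "relative" increase
    placement: str = "near"  # seedlings planted into the stand, or "uniform" over the grid

    def __post_init__(self) -> None:
        unknown = set(self.kinds) - VALID_KINDS
        if unknown:
            raise ValueError(f"unknown rescue kinds: {sorted(unknown)}")
        if not 0.0 <= self.p_s <= 1.0:
            raise ValueError("p_s must lie in [0, 1]")
        if "habitat" in self.kinds and self.phi_new is None:
            raise ValueError("habitat rescue requires phi_new")
        object.__setattr__(self, "kinds", frozenset(self.kinds))


def check_trigger(state: SimState, plan: Optional[RescuePlan]) -> bool:
    """True iff the plan should fire this year (strictly below threshold)."""
    if plan is None or not plan.kinds:
        return False
    if plan.fire_once and state.rescue_fired:
        return False
    return state.n_reproductive() < plan.trigger_threshold


def _local_seedling_genotypes(pop: Population, n: int, rng: np.random.Generator):
    """Genotypes built by per-locus allele-frequency sampling from ``pop``.

    Two independent draws per locus; the S locus is redrawn until
    heterozygous, unless the population carries a single S rank (then
    heterozygosity is unattainable and the homozygote is kept).
    """
    s_pool = pop.s.ravel()
    s = rng.choice(s_pool, size=(n, 2))
    if np.unique(s_pool).size > 1:
        homo = s[:, 0] == s[:, 1]
        while homo.any():
            s[homo] = rng.choice(s_pool, size=(int(homo.sum()), 2))
            homo = s[:, 0] == s[:, 1]
    neutral = np.empty((n, N_NEUTRAL_LOCI, 2), dtype=np.int16)
    for locus in range(N_NEUTRAL_LOCI):
        neutral[:, locus, :] = rng.choice(pop.neutral[:, locus, :].ravel(), size=(n, 2))
    return s, neutral


def _place_seedlings(
    state: SimState, s, neutral, rng: np.random.Generator, placement: str = "near"
) -> int:
    """Plant seedlings (age 0) on free suitable cells; returns number placed.

    ``placement="near"`` (default) restricts candidate cells to within
    pollen range of a surviving plant — introductions are planted into
    the existing stand, the way augmentation is done in practice, so
    they enter the residents' mating neighborhood.  ``"uniform"``
    scatters them over all free suitable cells of the grid.  Either
    way, if fewer free cells exist than seedlings, the surplus is
    dropped (shortfall visible as a smaller introduction).
    """
    free = state.landscape.free_suitable_cells()
    if placement == "near" and state.pop.n and len(free):
        from scipy.spatial import cKDTree

        pos = np.stack([state.pop.x, state.pop.y], axis=1).astype(np.float64)
        dist, _ = cKDTree(pos).query(free.astype(np.float64), k=1)
        near = free[dist <= state.params.pollen_range]
        if len(near):
            free = near
    elif placement != "uniform" and placement != "near":
        raise ValueError(f"placement must be 'near' or 'uniform', got {placement!r}")
    n = min(len(s), len(free))
    if n == 0:
        return 0
    cells = free[rng.choice(len(free), size=n, replace=False)]
    state.pop = state.pop.extended(cells[:, 0], cells[:, 1], np.zeros(n), s[:n], neutral[:n])
    state.landscape.occupied[cells[:, 1], cells[:, 0]] = True
    return n


def demographic_rescue(state: SimState, n: int, rng: np.random.Generator,
                       placement: str = "near") -> SimState:
    """Introduce ``n`` locally sourced seedlings (no new alleles possible)."""
    if state.pop.n == 0:
        return state
    s, neutral = _local_seedling_genotypes(state.pop, n, rng)
    _place_seedlings(state, s, neutral, rng, placement)
    return state


def _novel_source_pool(pop: Population, n_s: int, rng: np.random.Generator):
    """Mint an immigrant source pool: ``n_s`` fresh S ranks, 3 fresh ids per neutral locus."""
    base_s = int(pop.s.max()) if pop.n else 0
    s_pool = np.arange(base_s + 1, base_s + 1 + n_s)
    base_n = int(pop.neutral.max()) if pop.n else 0
    neutral_pool = np.arange(base_n + 1, base_n + 4)
    return s_pool, neutral_pool


def genetic_rescue(
    state: SimState,
    n: int,
    p_s: float,
    rng: np.random.Generator,
    novel_alleles: str = "both",
    source_s_alleles: int = 10,
    placement: str = "near",
) -> SimState:
    """Introduce ``n`` seedlings, each novel with probability ``p_s``.

    Novel immigrants carry a heterozygous pair of minted S ranks (or
    one minted + one local when ``novel_alleles == "one"``) and novel
    neutral alleles; the rest are locally sourced exactly as in
    demographic rescue.
    """
    if state.pop.n == 0:
        return state
    s, neutral = _local_seedling_genotypes(state.pop, n, rng)
    novel = rng.random(n) < p_s
    k = int(novel.sum())
    if k:
        s_pool, neutral_pool = _novel_source_pool(state.pop, source_s_alleles, rng)
        pairs = np.empty((k, 2), dtype=np.int32)
        for i in range(k):  # distinct pair per immigrant
            pairs[i] = rng.choice(s_pool, size=2, replace=False)
        if novel_alleles == "one":
            pairs[:, 1] = rng.choice(state.pop.s.ravel(), size=k)
        elif novel_alleles != "both":
            raise ValueError(f"novel_alleles must be 'both' or 'one', got {novel_alleles!r}")
        s[novel] = pairs
        neutral[novel] = rng.choice(neutral_pool, size=(k, N_NEUTRAL_LOCI, 2))
    _place_seedlings(state, s, neutral, rng, placement)
    return state


def habitat_rescue(state: SimState, phi_new: float, rng: np.random.Generator,
                   mode: str = "absolute") -> SimState:
    """Raise the suitable-site fraction; the population itself is untouched."""
    if mode == "relative":
        phi_new = min(1.0, state.landscape.phi * (1.0 + phi_new))
    elif mode != "absolute":
        raise ValueError(f"habitat_mode must be 'absolute' or 'relative', got {mode!r}")
    upgrade_suitability(state.landscape, phi_new, rng)
    return state


def apply_plan(state: SimState, plan: RescuePlan, rng: np.random.Generator,
               source_s_alleles: int = 10) -> SimState:
    """Fire every component of the plan, habitat first.

    Habitat goes first so introduced seedlings can land on newly
    suitable cells.  A plan containing the genetic kind with
    ``p_s = 0`` is deliberately identical in distribution to a
    demographic introduction.
    """
    if "habitat" in plan.kinds:
        habitat_rescue(state, plan.phi_new, rng, mode=plan.habitat_mode)
    if "genetic" in plan.kinds:
        genetic_rescue(state, plan.n_introduced, plan.p_s, rng,
                       novel_alleles=plan.novel_alleles, source_s_alleles=source_s_alleles,
                       placement=plan.placement)
    elif "demographic" in plan.kinds:
        demographic_rescue(state, plan.n_introduced, rng, placement=plan.placement)
    state.rescue_fired = True
    state.rescue_generation = state.generation
    return state
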