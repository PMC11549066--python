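"""The annual reproductive cycle of a self-incompatible perennial.

Each simulated year runs, in order:

1. **Reproduction** — every plant at or above the minimum reproductive
   age produces ``Ov`` ovules (age-linear fecundity, capped at ``b0``).
   For each ovule one pollen donor is drawn uniformly, with
   replacement, from the reproductive plants within pollen range; if
   the donor's sporophytic pollen phenotype matches either pistil
   allele the ovule is aborted (by default without redrawing a donor),
   otherwise an offspring genotype is built from one Mendelian gamete
   of each parent.
2. **Seed dispersal** — each seed lands uniformly on a cell of the
   (unclipped) dispersal disc around its mother; positions off the
   grid are lost (absorbing boundary).
3. **Adult mortality** — every adult dies independently with
   probability ``d``; its cell becomes free the same year.
4. **Establishment** — in each suitable, unoccupied cell where at
   least one seed landed, exactly one uniformly chosen seed germinates
   as an age-0 recruit; all other seeds die.
5. **Ageing** — survivors and recruits age by one year.

The per-ovule donor lottery is what produces the mate-availability
Allee effect: as S alleles are lost, the fraction of compatible donors
falls and with it per-capita seed set.

The object-level :func:`reproduce` is the readable single-mother
reference; :func:`annual_step` is the vectorised engine used for whole
simulations (scipy cKDTree neighbor search + numpy array kernels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .genetics import (
    N_NEUTRAL_LOCI,
    DiploidGenotype,
    compatible_arr,
    fuse,
    is_compatible,
    pollen_phenotype_arr,
    sample_gamete,
)
from .landscape import Landscape, disc_offsets

__all__ = [
    "SimParams",
    "Individual",
    "Population",
    "SimState",
    "StepStats",
    "ovule_count",
    "ovule_count_arr",
    "reproduce",
    "disperse",
    "mortality",
    "establish",
    "annual_step",
]


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters.

    ``d`` is the annual adult death probability, so ``1/d`` is the
    expected lifespan ``L``; fecundity ramps linearly with age and
    saturates at ``b0`` ovules exactly at age ``L``.  Defaults follow
    the headline study conditions (N0 = 250 plants on a 100 x 100 grid,
    d = 0.05, 10 founder S alleles, pollen range 10, seed range 5);
    ``b0`` and ``phi`` are the two knobs not dictated by the biology;
    the defaults (b0 = 1, phi = 0.144) come from calibrating the
    control scenario's mean persistence (see docs/methods.md).
    """

    d: float = 0.05
    b0: int = 1
    min_repro_age: int = 2
    pollen_range: float = 10.0
    seed_range: float = 5.0
    max_generations: int = 500
    initial_n: int = 250
    initial_s_alleles: int = 10
    phi: float = 0.144
    width: int = 100
    height: int = 100
    pistil_model: str = "codominant"
    metric: str = "euclidean"
    redraw_donor: bool = False
    initial_age: str = "uniform"  # "uniform" over {0..L} or "zero"

    def __post_init__(self) -> None:
        if not 0.0 < self.d <= 1.0:
            raise ValueError("d must lie in (0, 1]")
        if self.b0 < 0:
            raise ValueError("b0 must be >= 0")
        if min(self.pollen_range, self.seed_range) < 0:
            raise ValueError("ranges must be >= 0")

    @property
    def lifespan(self) -> float:
        """Expected adult lifespan L = 1/d."""
        return 1.0 / self.d


@dataclass(frozen=True)
class Individual:
    """Object-level view of one plant: genotype, age, lattice cell."""

    id: int
    genotype: DiploidGenotype
    age: int
    cell: tuple[int, int]


class Population:
    """Array-backed population: positions, ages and genotypes in lockstep.

    Columns: ``x``/``y`` int32 positions, ``age`` int32, ``s`` (n, 2)
    int32 S-allele ranks, ``neutral`` (n, 5, 2) int16 neutral alleles.
    """

    def __init__(self, x, y, age, s, neutral):
        self.x = np.asarray(x, dtype=np.int32)
        self.y = np.asarray(y, dtype=np.int32)
        self.age = np.asarray(age, dtype=np.int32)
        self.s = np.asarray(s, dtype=np.int32).reshape(-1, 2)
        self.neutral = np.asarray(neutral, dtype=np.int16).reshape(-1, N_NEUTRAL_LOCI, 2)
        n = len(self.x)
        if not (len(self.y) == len(self.age) == len(self.s) == len(self.neutral) == n):
            raise ValueError("population columns have mismatched lengths")

    @classmethod
    def empty(cls) -> "Population":
        return cls(
            np.empty(0), np.empty(0), np.empty(0),
            np.empty((0, 2)), np.empty((0, N_NEUTRAL_LOCI, 2)),
        )

    @property
    def n(self) -> int:
        return len(self.x)

    def reproductive_mask(self, min_repro_age: int) -> np.ndarray:
        return self.age >= min_repro_age

    def keep(self, mask: np.ndarray) -> "Population":
        return Population(self.x[mask], self.y[mask], self.age[mask], self.s[mask], self.neutral[mask])

    def extended(self, x, y, age, s, neutral) -> "Population":
        return Population(
            np.concatenate([self.x, np.asarray(x, dtype=np.int32)]),
            np.concatenate([self.y, np.asarray(y, dtype=np.int32)]),
            np.concatenate([self.age, np.asarray(age, dtype=np.int32)]),
            np.concatenate([self.s, np.asarray(s, dtype=np.int32).reshape(-1, 2)]),
            np.concatenate([self.neutral, np.asarray(neutral, dtype=np.int16).reshape(-1, N_NEUTRAL_LOCI, 2)]),
        )

    def genotype(self, i: int) -> DiploidGenotype:
        return DiploidGenotype(
            s=(int(self.s[i, 0]), int(self.s[i, 1])),
            neutral=tuple((int(a), int(b)) for a, b in self.neutral[i]),
        )

    def individual(self, i: int) -> Individual:
        return Individual(id=i, genotype=self.genotype(i), age=int(self.age[i]), cell=(int(self.x[i]), int(self.y[i])))

    def individuals(self) -> list[Individual]:
        return [self.individual(i) for i in range(self.n)]

    @classmethod
    def from_individuals(cls, inds: Sequence[Individual]) -> "Population":
        return cls(
            [p.cell[0] for p in inds],
            [p.cell[1] for p in inds],
            [p.age for p in inds],
            [p.genotype.s for p in inds],
            [p.genotype.neutral for p in inds],
        )

    def to_frame(self):
        """Tabular dump: one row per individual (id, x, y, age, s1, s2, n1a..n5b)."""
        import pandas as pd

        data = {"id": np.arange(self.n), "x": self.x, "y": self.y, "age": self.age,
                "s1": self.s[:, 0], "s2": self.s[:, 1]}
        for locus in range(N_NEUTRAL_LOCI):
            data[f"n{locus + 1}a"] = self.neutral[:, locus, 0]
            data[f"n{locus + 1}b"] = self.neutral[:, locus, 1]
        return pd.DataFrame(data)


@dataclass
class StepStats:
    """Per-generation bookkeeping recorded at reproduction time.

    ``seeds_pre`` counts fertilised ovules per reproductive plant
    (pre-dispersal); ``recruits_post`` counts that plant's established
    offspring (post-dispersal germinants).  Mate-availability fields
    follow the neighborhood convention: donors are reproductive plants
    within pollen range, excluding the focal plant.
    """

    n_total: int = 0
    n_reproductive: int = 0
    n_recruits: int = 0
    n_deaths: int = 0
    mate_availability_mean: float = float("nan")
    compatible_mates_mean: float = float("nan")
    n_compatible_repro: int = 0
    pollen_donors_per_female_mean: float = float("nan")
    seeds_pre: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    recruits_post: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))


@dataclass
class SimState:
    """Mutable simulation state threaded through :func:`annual_step`."""

    pop: Population
    landscape: Landscape
    params: SimParams
    generation: int = 0
    rescue_fired: bool = False
    rescue_generation: Optional[int] = None
    last_stats: Optional[StepStats] = None

    @property
    def extinct(self) -> bool:
        return self.pop.n == 0

    def n_reproductive(self) -> int:
        return int(self.pop.reproductive_mask(self.params.min_repro_age).sum())


# ---------------------------------------------------------------------------
# fecundity


def ovule_count(age: int, params: SimParams) -> int:
    """Ovules produced at a given age: round(b0 * d * A), capped at b0.

    The cap binds for ages above the expected lifespan L = 1/d; at
    A = L the ramp reaches b0 exactly.  Rounding is half-up for
    determinism across platforms.
    """
    if age * params.d <= 1.0:
        return int(np.floor(params.b0 * params.d * age + 0.5))
    return params.b0


def ovule_count_arr(age: np.ndarray, params: SimParams) -> np.ndarray:
    ramp = np.floor(params.b0 * params.d * age + 0.5)
    return np.where(age * params.d <= 1.0, ramp, params.b0).astype(np.int64)


# ---------------------------------------------------------------------------
# object-level reference operations (small populations, tests, examples)


def reproduce(
    mother: Individual,
    population: Sequence[Individual],
    landscape: Landscape,
    params: SimParams,
    rng: np.random.Generator,
) -> list[DiploidGenotype]:
    """Offspring genotypes of one mother for one year (pre-dispersal).

    Donors are reproductive plants within pollen range of the mother,
    herself excluded.  Each ovule draws one donor uniformly with
    replacement; an incompatible draw aborts that ovule (no redraw
    unless ``params.redraw_donor``).  With an empty donor pool the
    mother sets no seed at all.
    """
    if mother.age < params.min_repro_age:
        raise ValueError("mother is below the minimum reproductive age")
    mx, my = mother.cell
    r2 = params.pollen_range**2
    if params.metric == "chebyshev":
        def in_range(p):
            return max(abs(p.cell[0] - mx), abs(p.cell[1] - my)) <= params.pollen_range
    else:
        def in_range(p):
            return (p.cell[0] - mx) ** 2 + (p.cell[1] - my) ** 2 <= r2
    pool = [
        p for p in population
        if p.age >= params.min_repro_age and p.cell != mother.cell and in_range(p)
    ]
    if not pool:
        return []
    if params.redraw_donor:
        pool = [p for p in pool if is_compatible(p.genotype, mother.genotype, params.pistil_model)]
        if not pool:
            return []
    offspring = []
    for _ in range(ovule_count(mother.age, params)):
        donor = pool[rng.integers(len(pool))]
        if is_compatible(donor.genotype, mother.genotype, params.pistil_model):
            offspring.append(fuse(sample_gamete(mother.genotype, rng), sample_gamete(donor.genotype, rng)))
    return offspring


def disperse(
    mother_cell: tuple[int, int],
    landscape: Landscape,
    params: SimParams,
    rng: np.random.Generator,
) -> Optional[tuple[int, int]]:
    """One seed's landing cell, or None if it fell off the grid.

    The draw is uniform over the cells of the *unclipped* dispersal
    disc, so seeds near an edge are lost with the off-grid fraction of
    the disc.  Landing on an occupied or unsuitable cell still returns
    that cell; its fate is resolved at establishment.
    """
    offs = disc_offsets(params.seed_range, params.metric)
    dx, dy = offs[rng.integers(len(offs))]
    x, y = mother_cell[0] + int(dx), mother_cell[1] + int(dy)
    if not landscape.on_grid(np.array(x), np.array(y)):
        return None
    return (x, y)


def mortality(pop: Population, params: SimParams, rng: np.random.Generator) -> Population:
    """Independent survival lottery: each adult dies with probability d."""
    return pop.keep(rng.random(pop.n) >= params.d)


def establish(
    seed_cells: np.ndarray,
    seed_index: np.ndarray,
    landscape: Landscape,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices of the seeds that germinate, one per free suitable cell.

    ``seed_cells`` is (k, 2) landing positions, ``seed_index`` an
    aligned array of seed identifiers.  In every suitable unoccupied
    cell holding >= 1 seed a single uniformly chosen seed recruits;
    all other seeds die.
    """
    if len(seed_cells) == 0:
        return np.empty(0, dtype=seed_index.dtype)
    xs, ys = seed_cells[:, 0], seed_cells[:, 1]
    ok = landscape.suitable[ys, xs] & ~landscape.occupied[ys, xs]
    if not ok.any():
        return np.empty(0, dtype=seed_index.dtype)
    xs, ys, idx = xs[ok], ys[ok], seed_index[ok]
    cell_id = ys.astype(np.int64) * landscape.width + xs
    perm = rng.permutation(len(cell_id))
    _, first = np.unique(cell_id[perm], return_index=True)
    return idx[perm[first]]


# ---------------------------------------------------------------------------
# vectorised annual step


def _donor_pools(pos: np.ndarray, radius: float, metric: str):
    """CSR adjacency (counts, offsets, flat neighbor list) within ``radius``."""
    nr = len(pos)
    p = np.inf if metric == "chebyshev" else 2.0
    pairs = cKDTree(pos).query_pairs(radius, p=p, output_type="ndarray")
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    order = np.argsort(src, kind="stable")
    counts = np.bincount(src, minlength=nr)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    return counts, offsets, dst[order]


def _sample_alleles(pairs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One allele per row of an (k, ..., 2) diploid array, fair coin per locus."""
    bits = rng.integers(0, 2, size=pairs.shape[:-1])
    return np.take_along_axis(pairs, bits[..., None], axis=-1)[..., 0]


def annual_step(state: SimState, rng: np.random.Generator) -> SimState:
    """Advance the population by one year; records a :class:`StepStats`.

    Mate-availability statistics are measured at reproduction time,
    before mortality, over the reproductive plants only.
    """
    pop, land, params = state.pop, state.landscape, state.params
    stats = StepStats(n_total=pop.n)

    repro = pop.reproductive_mask(params.min_repro_age)
    m_idx = np.flatnonzero(repro)
    nr = len(m_idx)
    stats.n_reproductive = nr
    stats.seeds_pre = np.zeros(nr, dtype=np.int64)
    stats.recruits_post = np.zeros(nr, dtype=np.int64)

    seed_x = seed_y = seed_mother = None
    seed_s = seed_neutral = None

    if nr > 0:
        pos = np.stack([pop.x[m_idx], pop.y[m_idx]], axis=1).astype(np.float64)
        counts, offsets, flat = _donor_pools(pos, params.pollen_range, params.metric)
        stats.pollen_donors_per_female_mean = float(counts.mean())

        phen = pollen_phenotype_arr(pop.s[m_idx])
        s_repro = pop.s[m_idx]

        # mate availability over the directed donor graph
        if flat.size:
            src = np.repeat(np.arange(nr), counts)
            ok_edge = compatible_arr(phen[flat], s_repro[src], params.pistil_model)
            compat_counts = np.bincount(src, weights=ok_edge, minlength=nr)
        else:
            compat_counts = np.zeros(nr)
        stats.compatible_mates_mean = float(compat_counts.mean())
        stats.n_compatible_repro = int((compat_counts >= 1).sum())
        with_pool = counts > 0
        if with_pool.any():
            stats.mate_availability_mean = float((compat_counts[with_pool] / counts[with_pool]).mean())

        # per-ovule donor lottery, mothers with a non-empty pool only
        ovules = ovule_count_arr(pop.age[m_idx], params)
        if params.redraw_donor and flat.size:
            # restrict each pool to its compatible donors; redraw == uniform over them
            src = np.repeat(np.arange(nr), counts)
            keep = compatible_arr(phen[flat], s_repro[src], params.pistil_model)
            flat = flat[keep]
            counts = np.bincount(src[keep], minlength=nr)
            offsets = np.concatenate([[0], np.cumsum(counts)])
        active = (counts > 0) & (ovules > 0)
        if active.any():
            mother_local = np.repeat(np.flatnonzero(active), ovules[active])
            k = len(mother_local)
            draw = (rng.random(k) * counts[mother_local]).astype(np.int64)
            donor_local = flat[offsets[mother_local] + draw]
            fert = compatible_arr(phen[donor_local], s_repro[mother_local], params.pistil_model)
            mother_local, donor_local = mother_local[fert], donor_local[fert]
            stats.seeds_pre = np.bincount(mother_local, minlength=nr)

            mg, dg = m_idx[mother_local], m_idx[donor_local]
            seed_s = np.stack(
                [_sample_alleles(pop.s[mg], rng), _sample_alleles(pop.s[dg], rng)], axis=1
            )
            seed_neutral = np.stack(
                [_sample_alleles(pop.neutral[mg], rng), _sample_alleles(pop.neutral[dg], rng)],
                axis=2,
            )
            # dispersal over the unclipped disc; off-grid seeds are lost
            offs = disc_offsets(params.seed_range, params.metric)
            pick = offs[rng.integers(len(offs), size=len(mg))]
            seed_x = pop.x[mg] + pick[:, 0]
            seed_y = pop.y[mg] + pick[:, 1]
            on = land.on_grid(seed_x, seed_y)
            seed_x, seed_y = seed_x[on], seed_y[on]
            seed_mother = mother_local[on]
            seed_s, seed_neutral = seed_s[on], seed_neutral[on]

    # adult mortality, then occupancy reflects the survivors
    survive = rng.random(pop.n) >= params.d
    stats.n_deaths = int((~survive).sum())
    pop = pop.keep(survive)
    land.occupied.fill(False)
    land.occupied[pop.y, pop.x] = True

    # establishment: one germinant per free suitable seeded cell
    if seed_x is not None and len(seed_x):
        cells = np.stack([seed_x, seed_y], axis=1)
        germ = establish(cells, np.arange(len(seed_x)), land, rng)
        if len(germ):
            stats.recruits_post = np.bincount(seed_mother[germ], minlength=nr)
            pop = pop.extended(
                seed_x[germ], seed_y[germ], np.zeros(len(germ)),
                seed_s[germ], seed_neutral[germ],
            )
            land.occupied[seed_y[germ], seed_x[germ]] = True
    stats.n_recruits = int(stats.recruits_post.sum())

    pop.age += 1  # survivors and recruits alike
    state.pop = pop
    state.generation += 1
    state.last_stats = stats
    return state
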