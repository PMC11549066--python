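"""Per-generation output variables and per-replicate / per-scenario summaries.

The per-generation record carries the demographic, fitness and genetic
variables tracked by the study design: population and reproductive
counts, mate availability (proportion and count of compatible donors
within pollen range), seeds per plant post-dispersal (germinated
recruits per reproductive plant — the fitness measure), seed-count
variances before and after dispersal, S-allele richness, and F_IS.

Persistence is the generation of extinction, censored at the
simulation horizon; scenario tables report it both raw and as the
delta against a control mean.  "Long-term" levels of a variable are
its mean over a trailing window (default 100 generations) before
extinction or censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genetics import count_s_alleles_arr, fixation_index_arr, pollen_phenotype_arr
from .lifecycle import Population, SimParams, SimState, StepStats

__all__ = [
    "GenerationRecord",
    "ReplicateSummary",
    "record_generation",
    "mate_availability",
    "seed_stats",
    "records_to_frame",
    "summarize_replicate",
    "summarize_replicates",
]

#: per-generation variables that get "final-window" and time-averaged summaries
SUMMARY_FIELDS = (
    "n_total",
    "n_reproductive",
    "n_compatible_repro",
    "mate_availability_mean",
    "compatible_mates_mean",
    "seeds_per_plant_postdispersal",
    "s_allele_count",
    "f_is",
    "pollen_donors_per_female_mean",
)


@dataclass
class GenerationRecord:
    generation: int
    n_total: int
    n_reproductive: int
    n_compatible_repro: int
    mate_availability_mean: float
    compatible_mates_mean: float
    seeds_per_plant_postdispersal: float
    s_allele_count: int
    f_is: float
    pollen_donors_per_female_mean: float
    seed_variance_pre: float
    seed_variance_post: float
    n_recruits: int
    n_deaths: int


def mate_availability(pop: Population, params: SimParams) -> tuple[float, float]:
    """(mean proportion, mean count) of compatible donors per reproductive plant.

    For each reproductive plant the donor pool is every other
    reproductive plant within pollen range; the proportion is the
    compatible fraction of that pool (undefined for isolated plants
    and excluded from the proportion mean), the count its numerator
    (0 for isolated plants, included in the count mean).  Returns
    (nan, nan) for a population without reproductive plants.

    Direct quadratic computation; the simulation engine computes the
    same quantities incrementally and is cross-checked against this.
    """
    m = pop.reproductive_mask(params.min_repro_age)
    idx = np.flatnonzero(m)
    nr = len(idx)
    if nr == 0:
        return float("nan"), float("nan")
    x, y, s = pop.x[idx].astype(np.int64), pop.y[idx].astype(np.int64), pop.s[idx]
    phen = pollen_phenotype_arr(s)
    if params.metric == "chebyshev":
        dist_ok = np.maximum(np.abs(x[:, None] - x[None, :]), np.abs(y[:, None] - y[None, :])) <= params.pollen_range
    else:
        d2 = (x[:, None] - x[None, :]) ** 2 + (y[:, None] - y[None, :]) ** 2
        dist_ok = d2 <= params.pollen_range**2
    np.fill_diagonal(dist_ok, False)
    compat = (phen[None, :] != s[:, 0][:, None]) & (phen[None, :] != s[:, 1][:, None])
    if params.pistil_model == "dominant":
        compat = phen[None, :] != phen[:, None]
    counts = (dist_ok & compat).sum(axis=1)
    pool = dist_ok.sum(axis=1)
    with_pool = pool > 0
    prop = float((counts[with_pool] / pool[with_pool]).mean()) if with_pool.any() else float("nan")
    return prop, float(counts.mean())


def seed_stats(
    seeds_pre: np.ndarray, recruits_post: np.ndarray
) -> tuple[float, float, float]:
    """(mean recruits per mother, variance pre-dispersal, variance post-dispersal).

    Sample variances (ddof=1) over reproductive plants; NaN with fewer
    than two mothers, and NaN mean with none.
    """
    n = len(seeds_pre)
    if n == 0:
        return float("nan"), float("nan"), float("nan")
    var_pre = float(np.var(seeds_pre, ddof=1)) if n > 1 else float("nan")
    var_post = float(np.var(recruits_post, ddof=1)) if n > 1 else float("nan")
    return float(np.mean(recruits_post)), var_pre, var_post


def record_generation(state: SimState, stats: StepStats) -> GenerationRecord:
    """Assemble the per-generation record after an annual step.

    Genetic statistics (S-allele count, F_IS) are taken on the
    standing population at the end of the year.
    """
    pop = state.pop
    mean_post, var_pre, var_post = seed_stats(stats.seeds_pre, stats.recruits_post)
    return GenerationRecord(
        generation=state.generation,
        n_total=stats.n_total,
        n_reproductive=stats.n_reproductive,
        n_compatible_repro=stats.n_compatible_repro,
        mate_availability_mean=stats.mate_availability_mean,
        compatible_mates_mean=stats.compatible_mates_mean,
        seeds_per_plant_postdispersal=mean_post,
        s_allele_count=count_s_alleles_arr(pop.s),
        f_is=fixation_index_arr(pop.neutral),
        pollen_donors_per_female_mean=stats.pollen_donors_per_female_mean,
        seed_variance_pre=var_pre,
        seed_variance_post=var_post,
        n_recruits=stats.n_recruits,
        n_deaths=stats.n_deaths,
    )


def records_to_frame(records: Sequence[GenerationRecord], replicate: Optional[int] = None) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    if replicate is not None:
        df.insert(0, "replicate", replicate)
    return df


@dataclass
class ReplicateSummary:
    """One replicate's fate plus long-term and whole-run variable means."""

    replicate: int
    extinct: bool
    extinction_generation: int
    censored: bool
    rescue_generation: Optional[int] = None
    final_window: dict = field(default_factory=dict)
    time_average: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "replicate": self.replicate,
            "extinct": self.extinct,
            "extinction_generation": self.extinction_generation,
            "censored": self.censored,
            "rescue_generation": self.rescue_generation,
        }
        row.update({f"final_{k}": v for k, v in self.final_window.items()})
        row.update({f"avg_{k}": v for k, v in self.time_average.items()})
        return row


def summarize_replicate(
    df: pd.DataFrame,
    replicate: int,
    max_generations: int,
    extinct: bool,
    rescue_generation: Optional[int] = None,
    window: int = 100,
) -> ReplicateSummary:
    """Collapse a per-generation trajectory into a :class:`ReplicateSummary`.

    ``extinction_generation`` is the last recorded generation for an
    extinct run and ``max_generations`` (flagged censored) otherwise.
    The final window covers the trailing ``window`` generations of the
    trajectory.
    """
    if extinct:
        ext_gen = int(df["generation"].iloc[-1])
    else:
        ext_gen = max_generations
    tail = df.tail(window)

    def _nanmean(a: np.ndarray) -> float:
        a = a[np.isfinite(a)]
        return float(a.mean()) if a.size else float("nan")

    final = {k: _nanmean(tail[k].to_numpy(dtype=float)) for k in SUMMARY_FIELDS}
    avg = {k: _nanmean(df[k].to_numpy(dtype=float)) for k in SUMMARY_FIELDS}
    return ReplicateSummary(
        replicate=replicate,
        extinct=extinct,
        extinction_generation=ext_gen,
        censored=not extinct,
        rescue_generation=rescue_generation,
        final_window=final,
        time_average=avg,
    )


def summarize_replicates(
    summaries: Sequence[ReplicateSummary],
    control_mean_extinction: Optional[float] = None,
    control_means: Optional[dict] = None,
) -> pd.DataFrame:
    """Scenario-level table: mean and standard error of every summary column.

    Persistence is additionally reported as the delta of mean
    extinction generation against ``control_mean_extinction`` (censored
    replicates enter at the horizon).  When ``control_means`` supplies
    control values for a column, a percent-change column
    ``100 * (scenario - control) / control`` is added.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 replicates to summarize")
    df = pd.DataFrame([s.to_row() for s in summaries])
    num = df.select_dtypes(include=[np.number, bool]).astype(float)
    with np.errstate(all="ignore"):
        mean = num.mean()
        se = num.std(ddof=1) / np.sqrt(num.notna().sum())
    out = pd.DataFrame({"mean": mean, "se": se})
    if control_mean_extinction is not None:
        out.loc["persistence_delta", "mean"] = (
            mean["extinction_generation"] - control_mean_extinction
        )
    if control_means:
        for col, ref in control_means.items():
            if col in mean.index and ref not in (0, None) and np.isfinite(ref):
                out.loc[f"pct_change_{col}", "mean"] = 100.0 * (mean[col] - ref) / ref
    return out
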