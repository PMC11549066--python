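"""Scenario configuration, replicate orchestration, and experiment grids.

A scenario is a :class:`SimParams` plus an optional
:class:`~sirescue.rescue.RescuePlan` (no plan = control), run for a
number of independent replicates.  Replicate ``r`` of master seed
``s`` draws every random number from ``numpy``'s
``default_rng(SeedSequence((s, r)))`` stream, so trajectories are
bit-reproducible and replicates are order-independent.

The grid runner sweeps the study's factorial design — introduction
size N in {10..50}, novel-genotype probability p_s in {0, 0.2, .., 1},
habitat fraction phi_new in [0.25, 0.5] — and the calibrate helper
locates the (b0, phi) pair whose control scenario matches a target
mean extinction time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .landscape import generate_landscape
from .lifecycle import Population, SimParams, SimState, annual_step
from .metrics import (
    GenerationRecord,
    ReplicateSummary,
    record_generation,
    records_to_frame,
    summarize_replicate,
    summarize_replicates,
)
from .rescue import RescuePlan, apply_plan, check_trigger

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "initialize_state",
    "run_replicate",
    "run_experiment",
    "scenario_grid",
    "calibrate_control",
]


@dataclass(frozen=True)
class ExperimentConfig:
    sim: SimParams = field(default_factory=SimParams)
    rescue: Optional[RescuePlan] = None
    replicates: int = 100
    master_seed: int = 1
    label: str = "control"
    summary_window: int = 100

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimParams(**raw.get("sim", {}))
        rescue = None
        if raw.get("rescue"):
            r = dict(raw["rescue"])
            r["kinds"] = frozenset(r.get("kinds", []))
            rescue = RescuePlan(**r)
        keys = {"replicates", "master_seed", "label", "summary_window"}
        extra = {k: v for k, v in raw.items() if k in keys}
        return cls(sim=sim, rescue=rescue, **extra)

    def to_yaml(self, path) -> None:
        raw = {
            "sim": dataclasses.asdict(self.sim),
            "rescue": None,
            "replicates": self.replicates,
            "master_seed": self.master_seed,
            "label": self.label,
            "summary_window": self.summary_window,
        }
        if self.rescue is not None:
            r = dataclasses.asdict(self.rescue)
            r["kinds"] = sorted(r["kinds"])
            raw["rescue"] = r
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    records: pd.DataFrame  # one row per generation per replicate
    summaries: list[ReplicateSummary]
    scenario: pd.DataFrame  # scenario-level mean/se table

    @property
    def mean_extinction(self) -> float:
        return float(np.mean([s.extinction_generation for s in self.summaries]))

    def final_mean(self, key: str) -> float:
        return float(np.nanmean([s.final_window[key] for s in self.summaries]))

    def avg_mean(self, key: str) -> float:
        return float(np.nanmean([s.time_average[key] for s in self.summaries]))


def replicate_rng(master_seed: int, replicate_index: int) -> np.random.Generator:
    """Independent, reproducible stream for one replicate."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, replicate_index)))


def initialize_state(params: SimParams, rng: np.random.Generator) -> SimState:
    """Fresh landscape plus founder population.

    Founders sit on distinct uniformly chosen suitable cells, carry two
    distinct S ranks uniform over the founder set, neutral alleles
    uniform over {1, 2, 3}, and ages uniform over {0..L} (or all 0
    with ``initial_age="zero"``) to avoid a synchronized-cohort
    artifact.
    """
    land = generate_landscape(params.width, params.height, params.phi, rng)
    ys, xs = np.nonzero(land.suitable)
    if params.initial_n > len(xs):
        raise ValueError(
            f"initial_n={params.initial_n} exceeds {len(xs)} suitable cells (phi={params.phi})"
        )
    pick = rng.choice(len(xs), size=params.initial_n, replace=False)
    x, y = xs[pick], ys[pick]
    n = params.initial_n
    # founders are S-heterozygous: two distinct ranks per individual
    s = np.empty((n, 2), dtype=np.int32)
    s[:, 0] = rng.integers(1, params.initial_s_alleles + 1, size=n)
    shift = rng.integers(1, params.initial_s_alleles, size=n)
    s[:, 1] = (s[:, 0] - 1 + shift) % params.initial_s_alleles + 1
    neutral = rng.integers(1, 4, size=(n, 5, 2))
    if params.initial_age == "uniform":
        age = rng.integers(0, int(np.floor(params.lifespan)) + 1, size=n)
    elif params.initial_age == "zero":
        age = np.zeros(n, dtype=np.int64)
    else:
        raise ValueError(f"initial_age must be 'uniform' or 'zero', got {params.initial_age!r}")
    pop = Population(x, y, age, s, neutral)
    land.occupied[pop.y, pop.x] = True
    return SimState(pop=pop, landscape=land, params=params)


def run_replicate(
    config: ExperimentConfig, replicate_index: int
) -> tuple[pd.DataFrame, ReplicateSummary]:
    """One full trajectory: init, yearly steps with trigger checks, summary.

    The rescue trigger is evaluated before reproduction each year;
    the run ends at extinction or at ``max_generations``.
    Deterministic given (master_seed, replicate_index).
    """
    rng = replicate_rng(config.master_seed, replicate_index)
    state = initialize_state(config.sim, rng)
    records: list[GenerationRecord] = []
    for _ in range(config.sim.max_generations):
        if check_trigger(state, config.rescue):
            apply_plan(state, config.rescue, rng, source_s_alleles=config.sim.initial_s_alleles)
        annual_step(state, rng)
        records.append(record_generation(state, state.last_stats))
        if state.extinct:
            break
    df = records_to_frame(records, replicate=replicate_index)
    summary = summarize_replicate(
        df,
        replicate=replicate_index,
        max_generations=config.sim.max_generations,
        extinct=state.extinct,
        rescue_generation=state.rescue_generation,
        window=config.summary_window,
    )
    return df, summary


def run_experiment(
    config: ExperimentConfig,
    out_dir: Optional[Path] = None,
    control_mean_extinction: Optional[float] = None,
    progress: bool = False,
) -> ExperimentResult:
    """All replicates of one scenario; optionally writes tidy CSV outputs."""
    frames, summaries = [], []
    for r in range(config.replicates):
        df, summary = run_replicate(config, r)
        frames.append(df)
        summaries.append(summary)
        if progress:
            print(f"[{config.label}] replicate {r}: extinction={summary.extinction_generation}"
                  f"{' (censored)' if summary.censored else ''}")
    records = pd.concat(frames, ignore_index=True)
    scenario = summarize_replicates(summaries, control_mean_extinction)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        records.to_csv(out_dir / f"{config.label}_generations.csv", index=False)
        pd.DataFrame([s.to_row() for s in summaries]).to_csv(
            out_dir / f"{config.label}_replicates.csv", index=False
        )
        scenario.to_csv(out_dir / f"{config.label}_summary.csv")
        config.to_yaml(out_dir / f"{config.label}_config.yaml")
    return ExperimentResult(config=config, records=records, summaries=summaries, scenario=scenario)


def scenario_grid(
    base: ExperimentConfig,
    n_introduced: Sequence[int] = (10, 20, 30, 40, 50),
    p_s: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    phi_new: Sequence[float] = (0.25, 0.5),
    kinds: Sequence[str] = ("demographic", "genetic", "habitat"),
) -> list[ExperimentConfig]:
    """The factorial sweep of single-intervention scenarios, plus the control.

    Genetic rescue crosses N with p_s; demographic rescue sweeps N;
    habitat rescue sweeps phi_new.  Each combination appears exactly
    once, the control first.
    """
    configs = [dataclasses.replace(base, rescue=None, label="control")]
    if "demographic" in kinds:
        for n in n_introduced:
            plan = RescuePlan(kinds=frozenset({"demographic"}), n_introduced=n)
            configs.append(dataclasses.replace(base, rescue=plan, label=f"demographic_N{n}"))
    if "genetic" in kinds:
        for n in n_introduced:
            for ps in p_s:
                plan = RescuePlan(kinds=frozenset({"genetic"}), n_introduced=n, p_s=ps)
                configs.append(
                    dataclasses.replace(base, rescue=plan, label=f"genetic_N{n}_ps{ps:g}")
                )
    if "habitat" in kinds:
        for phi in phi_new:
            plan = RescuePlan(kinds=frozenset({"habitat"}), phi_new=phi)
            configs.append(dataclasses.replace(base, rescue=plan, label=f"habitat_phi{phi:g}"))
    return configs


def calibrate_control(
    base: ExperimentConfig,
    b0_values: Sequence[int],
    phi_values: Sequence[float],
    replicates: int = 10,
    max_generations: int = 1000,
    progress: bool = False,
) -> pd.DataFrame:
    """Sweep (b0, phi) and report control-scenario mean extinction times.

    Used to pin down the two parameters the study design leaves free,
    by matching the control's mean persistence to a target value.
    Returns one row per combination with the mean extinction
    generation, the fraction of censored runs, and the whole-run means
    of seed set and compatible-mate count.
    """
    rows = []
    for b0 in b0_values:
        for phi in phi_values:
            sim = dataclasses.replace(
                base.sim, b0=int(b0), phi=float(phi), max_generations=max_generations
            )
            cfg = dataclasses.replace(
                base, sim=sim, rescue=None, replicates=replicates,
                label=f"calib_b0{b0}_phi{phi:g}",
            )
            res = run_experiment(cfg)
            rows.append(
                {
                    "b0": b0,
                    "phi": phi,
                    "mean_extinction": res.mean_extinction,
                    "frac_censored": float(np.mean([s.censored for s in res.summaries])),
                    "avg_seeds_per_plant": res.avg_mean("seeds_per_plant_postdispersal"),
                    "avg_compatible_mates": res.avg_mean("compatible_mates_mean"),
                    "final_n_reproductive": res.final_mean("n_reproductive"),
                }
            )
            if progress:
                print(rows[-1])
    return pd.DataFrame(rows)
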