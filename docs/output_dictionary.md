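# Output dictionary

## Per-generation file (`<label>_generations.csv`)

One row per generation per replicate. All mate/seed statistics are
measured at reproduction time within the year; genetic statistics on
the standing population at the end of the year.

| column | meaning |
|---|---|
| `replicate` | replicate index (0-based) |
| `generation` | year counter, 1 = after the first annual cycle |
| `n_total` | population size at reproduction time |
| `n_reproductive` | plants at or above the minimum reproductive age (default 2) |
| `n_compatible_repro` | reproductive plants with >= 1 compatible donor within pollen range |
| `mate_availability_mean` | mean over non-isolated reproductive plants of (compatible donors / donors in range) |
| `compatible_mates_mean` | mean count of compatible donors in range over all reproductive plants (0 for isolated plants) |
| `seeds_per_plant_postdispersal` | germinated recruits this year per reproductive plant (the fitness measure) |
| `s_allele_count` | distinct S-allele ranks in the population |
| `f_is` | fixation index 1 - H_o/H_e averaged over polymorphic neutral loci; empty when undefined (monomorphic or n < 2) |
| `pollen_donors_per_female_mean` | mean number of reproductive plants within pollen range |
| `seed_variance_pre` | sample variance over mothers of fertilized ovules (pre-dispersal) |
| `seed_variance_post` | sample variance over mothers of established recruits |
| `n_recruits` | germinants this year |
| `n_deaths` | adult deaths this year |

## Per-replicate file (`<label>_replicates.csv`)

One row per replicate: `extinct`, `extinction_generation` (censored at
the horizon when not extinct), `censored`, `rescue_generation` (year
the plan fired, empty if never), plus `final_<var>` (mean of `<var>`
over the trailing 100 generations before extinction/censoring) and
`avg_<var>` (mean over the whole trajectory) for each variable listed
above from `n_total` through `pollen_donors_per_female_mean`.

## Scenario summary (`<label>_summary.csv`)

Mean and standard error of every per-replicate column; optionally
`persistence_delta` (mean extinction generation minus a supplied
control mean) and `pct_change_<col>` columns
(`100 * (scenario - control) / control`).

Coordinates in all dumps are 0-based integer (x = column, y = row) on
the `width x height` lattice.
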