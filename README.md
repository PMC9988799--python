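# survexpect

Observed overall survival versus life-table-predicted life expectancy in
registry-style cancer cohorts.

## The problem

Treatment guidelines for localized prostate cancer gate curative therapy
(radical prostatectomy, RP, or external beam radiotherapy, EBRT) on a
patient's life expectancy, usually estimated from age-based period life
tables such as the Social Security Administration's. Those tables are not
stratified by race/ethnicity, so a natural question for registry data is:
within each race/ethnicity × treatment stratum, does the cohort's *observed*
overall survival (OS) match the life expectancy (LE) the life table predicts
for a general-population group with the same age composition?

`survexpect` implements that comparison end to end for epidemiologists and
outcomes researchers working with SEER-like cohorts:

1. **Life table** — a period table of annual conditional death probabilities
   `q_x` (probability of dying in `[x, x+1)` given alive at exact age `x`).
2. **Predicted LE** — a Monte-Carlo Markov chain: each simulated patient
   starts at their attained age and in each of ten annual intervals either
   dies (probability `q_x` at the current age) or survives and ages one year.
   The fraction alive per year, averaged over replicates, is the predicted
   curve `LE(t)`; its exact limit is the product form
   `S(k | a) = ∏_{j<k} (1 − q_{a+j})`, available as an analytic fast path.
3. **Observed OS** — the Kaplan–Meier product-limit estimator
   `Ŝ(t) = ∏_{t_i ≤ t} (1 − d_i / n_i)` under right censoring, implemented
   from first principles together with the two-group log-rank test and the
   Pearson chi-square test of proportions.
4. **Comparison** — the yearly difference curve `Δ(t) = OS(t) − LE(t)` in
   percentage points, per (race/ethnicity, treatment) stratum, with the
   LE simulation run on each stratum's exact age multiset.

Because real registry records are access-restricted, the package ships a
first-class synthetic-data module that generates a Gompertz life table and an
eight-stratum cohort with realistic age mixtures, D'Amico intermediate/high-
risk tumor fields (PSA, clinical T stage, Gleason Grade Group, nodal stage),
and a per-stratum ground-truth *excess-hazard multiplier* `m` scaling the
life-table hazards: `m = 1` makes OS track LE exactly, `m > 1` produces a
survival deficit, `m < 1` a survival advantage.

## Worked example

```python
from survexpect import (default_config, generate_life_table, generate_cohort,
                        apply_eligibility, run_stratified_analysis, AnalysisConfig)

config = default_config(seed=11)
table = generate_life_table(config.lifetable_params)
records = generate_cohort(config, table)
kept, exclusions = apply_eligibility(records)
results, _ = run_stratified_analysis(kept, table, AnalysisConfig(seed=11, n_replicates=1000))
print(f"{len(kept)} of {len(records)} records analyzable")
for r in results:
    print(f"{r.stratum[0]:>5}-{r.stratum[1]:<4} n={r.n:<5} "
          f"OS(10)={r.os_annual[10]:5.1f}%  LE(10)={r.le_annual[10]:5.1f}%  "
          f"delta(10)={r.delta_annual[10]:+5.1f} pp")
```

prints

```
5538 of 5538 records analyzable
  NHW-RP   n=1995  OS(10)= 80.6%  LE(10)= 72.1%  delta(10)= +8.5 pp
  NHW-EBRT n=2054  OS(10)= 56.7%  LE(10)= 53.9%  delta(10)= +2.8 pp
  NHB-RP   n=297   OS(10)= 76.8%  LE(10)= 76.1%  delta(10)= +0.7 pp
  NHB-EBRT n=422   OS(10)= 55.5%  LE(10)= 62.7%  delta(10)= -7.2 pp
 HISP-RP   n=241   OS(10)= 75.1%  LE(10)= 71.4%  delta(10)= +3.7 pp
 HISP-EBRT n=231   OS(10)= 54.5%  LE(10)= 52.9%  delta(10)= +1.6 pp
ASIAN-RP   n=124   OS(10)= 79.8%  LE(10)= 65.5%  delta(10)=+14.4 pp
ASIAN-EBRT n=174   OS(10)= 58.6%  LE(10)= 47.3%  delta(10)=+11.3 pp
```

Reading the output: `OS(10)` is the Kaplan–Meier 10-year survival of the
stratum, `LE(10)` the Monte-Carlo life-table prediction for the same ages,
and `delta(10)` their difference in percentage points. The synthetic
defaults encode a known ground truth — most strata outlive their life-table
prediction (positive delta), the non-Hispanic Black RP stratum follows it
almost exactly, and the non-Hispanic Black EBRT stratum falls below it — so
the pipeline's job is to recover exactly that pattern from the simulated
follow-up records, which it does above.

The same analysis is available from the shell:

```sh
survexpect synth --out data/ --seed 11
survexpect run --cohort data/cohort.csv --lifetable data/lifetable.csv \
    --out analysis/ --seed 11 --replicates 1000
```

which writes a Table-1-style descriptive summary, per-stratum comparison
tables, long and wide difference tables, and a manifest recording the seed,
configuration, and exclusion log. `survexpect le`, `km`, and `describe`
expose the individual stages.

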