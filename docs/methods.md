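# Methods

## Model and procedure

The package compares two survival curves per cohort stratum over a 10-year
horizon.

**Predicted life expectancy.** A period life table supplies `q_x`, the
conditional probability of death within `[x, x+1)` for a person alive at
exact age `x`. A simulated patient of attained age `a` walks a two-state
Markov chain: in each annual interval they die with probability `q` at their
current age (absorbing) or survive and age one year. For a cohort the chain
is run on the *exact age multiset* of the stratum; one replicate's curve is
the fraction alive at the end of each year, and the prediction `LE(t)` is
the mean over replicates, with the across-replicate standard error reported
as the Monte-Carlo spread. The chain has a closed-form limit,
`S(k | a) = ∏_{j=0}^{k-1} (1 − q_{a+j})`, which serves both as an analytic
fast path (`le_from_closed_form`) and as the internal oracle against which
the Monte-Carlo engine is property-tested (agreement within 4 Monte-Carlo
standard errors on randomized table/cohort pairs).

Assumptions: a single period table applies to all calendar years of the
horizon and to all race/ethnicity groups, so predicted differences between
groups arise solely from age composition; ages are integer attained ages
(fractional ages at diagnosis are floored); mortality beyond the table's
terminal age is absorbing (`q = 1`), and by default the age path is clamped
to that absorbing value when it runs off the table ("clamp" policy; a
"strict" policy raises instead).

**Observed survival.** The Kaplan–Meier product-limit estimator
`Ŝ(t) = ∏_{t_i ≤ t} (1 − d_i / n_i)` over distinct death times, with the
standard tie rule (deaths precede censorings, so a subject censored at `t_i`
is still at risk there). The annual readout takes the step-function value at
exactly `k` years, so a death at an integer time is reflected at that year;
administrative censoring at the horizon is never an event. Greenwood's
variance is computed and stored but is not part of headline outputs, since
the comparison is descriptive. The two-group log-rank test (hypergeometric
observed-minus-expected with 1 df) and Pearson's chi-square of proportions
(no continuity correction) accompany the curves; all three estimators are
written from first principles and are cross-validated in the test suite
against an independent survival library (lifelines) and scipy, which are
never on the computation path.

**Comparison.** `Δ(t) = OS(t) − LE(t)` in percentage points on the shared
annual grid, per (race/ethnicity × treatment) stratum. Reported tables are
rounded half-up to one decimal; all stored values and test comparisons are
unrounded. No cross-stratum significance test is attached to Δ — the
contrast is descriptive by design.

## Cohort model

Records carry age at diagnosis, race/ethnicity (NHW / NHB / HISP / ASIAN,
plus NATIVE and UNKNOWN tokens that are excluded), treatment (RP / EBRT),
PSA, clinical T stage, Gleason Grade Group (GGG), clinical N stage,
metastatic status, follow-up years, and an event flag. D'Amico risk:
intermediate = cT2b and/or PSA in [10, 20] ng/ml and/or GGG 3; high = ≥cT2c
and/or PSA > 20 and/or GGG ≥ 4, with high dominating. PSA exactly 10 or 20
defaults into intermediate (low risk is conventionally PSA < 10); both
boundaries are toggles, and excluding 20 from intermediate moves it to high
(the tiers partition at the cut). Unsubstaged "cT2" maps to cT2a by default
(conservative). A missing field does not block classification when another
criterion fires; otherwise the record is unclassifiable and excluded under
its own reason. The eligibility filter keeps intermediate/high-risk M0
records in the four analyzable groups, retains cN1 and cNX, and tallies
exclusions under the first matching reason in the fixed order: unknown
metastatic status, unknown race, Native American, low risk, unclassifiable.
Descriptive summaries report medians with 25th/75th percentiles by linear
interpolation (R's default quantile definition) and half-up one-decimal
percentages.

## Synthetic data: what it emulates and what it does not

The generator stands in for restricted registry data. It emulates: eight
race × treatment strata at one-tenth a realistic national-registry scale (≈5,500
records; configurable); per-stratum age mixtures as truncated normals with
realistic per-stratum medians and treatment-level IQR spreads (σ = IQR/1.349,
floored to integers, clipped to the table range); tumor fields drawn so each
record provably classifies to its intended tier (with an optional low-risk
contamination fraction); nodal-stage frequencies near a realistic registry mix;
and death times drawn by walking the life table with per-year probability
`min(1, m · q_x)`, jittered uniformly within the death year so event times
are distinct, with administrative censoring at 10 years.

The default excess multipliers (NHW 0.70/0.95, NHB 1.00/1.30, HISP
0.67/0.82, ASIAN 0.62/0.65 for RP/EBRT) encode the qualitative ground truth
the analysis should recover: most strata outlive the life-table prediction,
the NHB-RP stratum follows it almost exactly, and NHB-EBRT falls below it.
They are fixed package defaults, not fitted quantities.

Not emulated: correlation structure among PSA, stage, and grade; cause of
death and competing risks; calendar-time incidence or table updating;
loss to follow-up before the horizon (all censoring is administrative); and
any real-world registry heterogeneity. Passing tests therefore demonstrate
that the pipeline recovers a *known multiplicative* deviation from a
life-table law under clean conditions — not that real cohorts deviate this
way, nor that the synthetic magnitudes equal those of any real cohort.

## Numerical choices

- Monte-Carlo default 1,000 replicates: the replicate SE of the curve is
  below 0.5 percentage points for cohorts of ≥1,000. One root seed expands
  into per-replicate substreams (`numpy.random.SeedSequence.spawn`), so
  results are independent of evaluation order; identical seeds give
  bit-identical output.
- Year grid: year `k` means "alive at the end of interval `k`", intervals
  `[k−1, k)`, matching annual life-table intervals; curves start at 1.
- Closed-form composition `S(k+m|a) = S(k|a)·S(m|a+k)` holds to 1e-12 and is
  property-tested.
- Strata smaller than 30 records (configurable) are skipped with a warning
  rather than producing unstable curves.
- The excess-multiplier fit solves `mean_i ∏_k (1 − min(1, m·q_ik)) =
  Ŝ(10)` by Brent's method on [0.05, 5]; if the observed value is outside
  the achievable range the nearer bracket end is returned.
- Degenerate statistics: a log-rank comparison with no deaths (or zero
  variance) returns statistic 0, p = 1; a chi-square table with a zero
  margin raises.

## Problem sizes in the shipped experiments

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which the binomial/Monte-Carlo error bands are far tighter
than the effects being checked: oracle-equivalence property tests use
cohorts of ≤60 at 300 replicates; null calibration uses 200 generated
cohorts of 2,000 for each of two age mixtures (surgical-age and
radiotherapy-age); multiplier recovery uses cohorts of 5,000; type-I-error
checks use 1,000 simulated null datasets.

## Known limitations

- A single sex-free period table; no cohort (generation) tables and no
  calendar-year interpolation across the horizon.
- Integer-year mortality resolution in the predicted arm, versus
  continuous-time (jittered) observed event times; at the annual readout
  grid this is exact, between grid points the predicted curve is a step.
- The eligibility filter assumes upstream parsing has already rejected
  malformed rows; it never errors.
- `fit_excess_multiplier` matches only the 10-year endpoint; a
  whole-curve fit would be more efficient but the endpoint match is the
  estimand the difference curve targets.
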