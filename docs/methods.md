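# Methods

## Exposure model

Short-term occupational exposure concentrations are treated as lognormal
throughout, the standard assumption for airborne contaminants. For task
*j* and worker *i*, concentrations *C*<sub>ij</sub> are lognormal with
worker-specific geometric mean; worker GMs are themselves lognormal around
the task GM. On the natural-log scale this is the one-way random-effects
model

    ln C = mu_j + b_i + e,   b_i ~ N(0, sigma2_B),  e ~ N(0, sigma2_W)

with total log-variance `ln²(GSD_j) = sigma2_B + sigma2_W`. The
`between_fraction` parameter is `sigma2_B / (sigma2_B + sigma2_W)`.

**Worker fits and aggregation.** Per-worker log-moments use the n−1
denominator. Workers contributing a single sample get their within-worker
SD imputed from the task's pooled within-worker SD (df-weighted over
multi-sample workers), so tasks with tiny n (the inlet task has two
samples) remain usable. Worker fits are aggregated with equal weight per
worker — the worker, not the sample, is the unit of inference, and equal
weighting keeps a heavily sampled worker from dominating. The aggregate
lognormal is moment-matched on the log scale to the equal-weight mixture:
its log-mean is the mean of worker log-means; its log-variance is the
(n−1) variance of worker log-means plus the mean worker log-variance. A
lognormal is not the mixture itself; tests check that its median tracks
the brute-force mixture median within 10% for moderate spreads.

**Variance components.** One-way ANOVA (method-of-moments) on log
concentrations, with the standard unbalanced divisor
`n0 = (N − Σn_i²/N)/(k − 1)`; a negative between-worker estimate is
truncated to zero. For balanced data this equals the REML estimate
(cross-checked against statsmodels MixedLM in the tests).

## Full-shift TWA simulation

A rotation scenario fixes task minutes `t_js ≥ 0` with `Σ t_js ≤ 480`;
the remainder `t6` is zero-exposure time (office work, breaks, offsite).
A simulated workday draws one concentration per task from the aggregated
task lognormal — independently across tasks, one draw per task per day —
and computes `TWA = Σ_j C_j t_js / 480`. Sampling uses the aggregated
task distribution rather than a two-stage worker-then-day draw: the
aggregate mixture already represents "a random worker". Each scenario is
simulated for 10,000 workdays (configurable); per-scenario RNG substreams
derive from `(seed, crc32(scenario_id))`, and per-task generator
substreams from `(seed, crc32(sample_type:task))`, so adding a scenario
or task never perturbs the others' draws.

The eight default scenarios use the observed task-duration statistics
(mean and range, minutes): S1/S2 run the thermal dryer at its max/min
observed duration (105/48) with inlet, mechanical dewatering and solar
dehydration at their means (75/96/53); S3/S4 drop the dryer and run those
three at max/min; S5/S6 also drop solar dehydration (inlet + dewatering
at max/min); S7/S8 are the waste-collection team doing latrine emptying
only at max/min duration (251/73), reflecting the separation between the
collection and plant teams.

Summaries: GM/GSD by log-moments (n−1), AM/SD by raw moments, 95th
percentile as the empirical type-7 quantile (linear interpolation between
order statistics — the common default; the choice is invisible at 10,000
draws). Rounding to two significant figures happens only at render time;
persisted values keep full precision.

## Exceedance and acceptability

Exceedance is the probability that a randomly selected worker's 8-h TWA
exceeds the OEL (90 EU/m³) on a randomly selected day, deemed acceptable
when strictly below 0.10. Two estimates are reported side by side,
because the published description of which concentrations the variance
decomposition was applied to is ambiguous:

* **empirical** — the fraction of simulated TWA draws strictly above the
  OEL;
* **parametric** — the lognormal tail
  `Phi((mu_ln − ln OEL)/sqrt(sigma2_B + sigma2_W))`, applied to the
  log-moments of the scenario's TWA draws (and available for any
  `VarianceComponents`, e.g. fitted task concentrations).

The two agree within Monte Carlo error whenever the TWA distribution is
well approximated by a lognormal; sums of lognormals are not exactly
lognormal, so small systematic differences appear for multi-task
scenarios. The published per-scenario exceedance column cannot be
reconciled with either definition (its printed values are inconsistent
with its own printed TWA GM/GSDs); this package reports both defined
estimators and does not attempt to reverse-engineer the discrepancy.

## Synthetic campaign generator

The generator emulates the source campaign's design: five tasks, 13
task-exclusive personal workers (latrine 3, inlet 1, dewatering 3, solar
3, dryer 3 — the published design gives totals, not the per-task worker
split; unbalanced totals are distributed round-robin), 42 personal
samples plus 20 area samples of the latrine task assigned to four
pseudo-location ids and treated by the same two-level model. Per-task
defaults (GM, GSD, duration range) are the published campaign summaries;
pump flows are uniform on 1.0–3.5 L/min and durations uniform on the
observed per-task range — uniform rather than normal, because the ranges
are published and bounded while a normal with the published mean/SD could
go negative.

`between_fraction` defaults to 0.3, a typical occupational-hygiene
variance split; the campaign reports only total GSDs, so the split is a
free parameter of the generator, overridable per task.

**Censoring.** The assay LOD is 0.15 EU per mL of extract with a 5 mL
extraction volume, i.e. 0.75 EU per filter; each sample's concentration
LOD follows from its own air volume (`flow × duration / 1000` m³).
Censored values are substituted at LOD/√2, the standard convention when
only the LOD is known.

What the generator does *not* emulate: seasonality, correlation of task
concentrations within a day, aerosol physics or spatial structure of area
samples, day-to-day autocorrelation, and measurement error of the assay
itself. Passing tests therefore demonstrate correctness of the estimators
and simulator under the stated lognormal random-effects model, not
robustness to real-world violations of it.

## Numerical and design choices

* GSD of a single value is undefined (NaN), never 1.
* `gsd = 1` generates exact point masses (multiplicative form avoids
  `exp(log(x))` round-off).
* All-zero-exposure scenarios report AM = SD = P95 = 0 with undefined
  GM/GSD rather than failing.
* The acceptability threshold is a strict inequality (`exceedance < 0.10`).
* Exceedance compares single-day TWAs to the OEL, not the long-run mean.
* Problem sizes in the test suite are chosen so that each tolerance band
  is ≥ 3 standard errors of the quantity under test wherever the check is
  stochastic; calibration checks at the published sample sizes (n = 9 and
  11) use the clustered-design standard error
  `ln(GSD)·sqrt(bf/k + (1−bf)/n)`, since with worker random effects the
  between-worker component only averages out over workers, not samples.
* End-to-end runs are byte-reproducible for a fixed seed and
  configuration; outputs carry the seed and a configuration hash, and no
  output embeds a timestamp.

## Known limitations

* The equal-weight lognormal aggregation is one defensible reading of
  "aggregating worker distributions"; sample-weighted or hierarchical
  Bayesian alternatives would shift task GSDs, especially for tasks with
  unbalanced worker contributions.
* Censored-lognormal maximum-likelihood fitting is out of scope; LOD/√2
  substitution biases GMs slightly upward when censoring is heavy (it is
  light at the default parameters).
* With 62 samples a campaign pins down task GMs only to within a factor
  of ~1.6–2 (two clustered log-SEs), so pipeline outputs fitted from one
  synthetic campaign vary noticeably between seeds; that variability is a
  faithful property of the design, not noise to be suppressed.
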