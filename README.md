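# endotwa

Task-based occupational exposure assessment for inhaled endotoxin, built for
settings where full-shift measurements are impractical: workers of fecal
sludge collection and resource-recovery (sludge-to-fuel) processes, sampled
per task rather than per shift.

Endotoxin (the lipopolysaccharide of Gram-negative bacterial cell walls,
measured in endotoxin units, EU) is a pro-inflammatory agent of organic
dusts. Occupational limits are expressed as 8-h time-weighted averages
(TWA) — here the health-based limit of **90 EU/m³** proposed by the Health
Council of the Netherlands (DECOS) — but task-based samples cover only part
of a shift. `endotwa` bridges the two:

1. **Task distributions.** Personal air samples are summarised per task by
   geometric mean and geometric standard deviation (GM, GSD); per-worker
   lognormal fits *C*<sub>ij</sub> are aggregated (equal weight per worker,
   moment-matched on the log scale) into one lognormal *C*<sub>j</sub> per
   task *j*, and within/between-worker variance components are estimated by
   one-way random-effects ANOVA on log concentrations.
2. **Monte Carlo 8-h TWA.** A rotation scenario *s* fixes the minutes
   *t*<sub>js</sub> spent in each task (remainder of the 480-min shift at
   zero exposure). A simulated workday draws one concentration per task and
   computes TWA<sub>s</sub> = Σ<sub>j</sub> *C*<sub>j</sub>·*t*<sub>js</sub>/480;
   10,000 workdays give the full-shift exposure distribution per scenario.
3. **Exceedance vs the OEL.** The probability γ that a random worker's
   exposure on a random day exceeds the OEL, computed empirically from the
   simulated draws and parametrically as
   Φ((μ<sub>ln</sub> − ln OEL)/√(σ²<sub>B</sub> + σ²<sub>W</sub>));
   conventionally acceptable when γ < 0.10.

A synthetic-campaign generator (two-level lognormal with worker random
effects, uniform task durations and pump flows, limit-of-detection censoring
with LOD/√2 substitution) reproduces the structure of the source campaign —
5 tasks, 13 workers, 42 personal + 20 area samples — so the whole pipeline
is testable without access to raw measurements.

## Worked example

```python
from endotwa import PipelineConfig, run_pipeline

paths = run_pipeline(PipelineConfig(seed=42, output_dir="outputs"))
print(open(paths["table2_txt"]).read())
```

which prints (seed 42, built-in campaign and the eight default rotation
scenarios):

```
Scenario  Description                                               Iterations  GM (GSD)   AM (SD)    95th Percentile  Exceedance (empirical)  Exceedance (parametric)  Acceptable
--------  --------------------------------------------------------  ----------  ---------  ---------  ---------------  ----------------------  -----------------------  ----------
S1        thermal dryer at max duration; other plant tasks at mean  10000       580 (1.7)  660 (410)  1300             1.0                     1.0                      False
S2        thermal dryer at min duration; other plant tasks at mean  10000       310 (1.7)  360 (270)  750              1.0                     0.99                     False
S3        no dryer; other plant tasks at max duration               10000       91 (2.7)   180 (650)  610              0.43                    0.50                     False
S4        no dryer; other plant tasks at min duration               10000       28 (2.5)   53 (140)   180              0.12                    0.11                     False
S5        no dryer, no solar; inlet and dewatering at max duration  10000       28 (1.8)   35 (38)    84               0.043                   0.020                    True
S6        no dryer, no solar; inlet and dewatering at min duration  10000       10 (1.5)   11 (9.2)   21               0.00090                 0.000000092              True
S7        latrine emptying only, max duration                       10000       25 (1.8)   29 (18)    62               0.011                   0.011                    True
S8        latrine emptying only, min duration                       10000       7.1 (1.8)  8.3 (5.1)  18               0                       0.0000034                True
```

Reading it: each row is one rotation schedule. Scenarios containing the
thermal-drying task (S1–S2) have full-shift GMs far above the 90 EU/m³ OEL
and exceedance ≈ 1 — the dryer dominates any schedule that includes it.
Dropping the dryer and the solar greenhouse (S5–S6) brings the 95th
percentile below the OEL and the exceedance under the 0.10 acceptability
bound. Because this run fits task distributions to one synthetic campaign of
62 samples, the numbers wobble between seeds exactly as a real small
campaign would; simulating directly from the published task GM/GSDs (see
`scripts/acceptance.py`) gives e.g. scenario-1 GM ≈ 880 EU/m³.

The same pipeline is available from the shell:

```sh
endotwa generate --seed 42 --out campaign.csv
endotwa stats --in campaign.csv --out table1.csv
endotwa simulate --stats table1.csv --n-iter 10000 --seed 42 --out table2.csv
endotwa comply --in table2.csv --oel 90 --threshold 0.10
endotwa run --seed 42 --output-dir outputs   # all of the above at once
```

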