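# sedtrack

Accelerometer data reduction, sedentary-accumulation metrics and
longitudinal **tracking** analysis for pooled youth cohorts.

Children's sedentary time is usually measured with waist-worn uniaxial
accelerometers that accumulate movement counts over 60-s epochs. Pooled
multi-study databases ask two questions of such data: how does sedentary
time change with age, and how stable is a child's *rank* in the population
over time (tracking)? `sedtrack` implements the full chain needed to answer
them reproducibly:

1. **Data reduction** — reintegration of sub-minute epochs to 60 s,
   invalidation of implausible spikes (> 30,000 cpm), restriction to the
   07:00–24:00 waking window, non-wear detection as runs of ≥ 60 consecutive
   zero-count minutes (no tolerance), valid-day screening (≥ 480 worn
   minutes) and participant inclusion (≥ 4 valid days including ≥ 1 weekend
   day at baseline *and* at least one follow-up wave).
2. **Outcomes** — per valid day: total sedentary time (worn minutes
   < 100 cpm), prolonged sedentary time (minutes inside uninterrupted
   sedentary bouts ≥ 10 min), MVPA (≥ 3000 cpm); per wave: means over valid
   days and the **day-to-day variation**

   $$\mathrm{DTD} = \frac{\sum_i \lvert x_i - \bar{x}\rvert}{N}$$

   the mean absolute deviation of a daily metric over the N measurement days.
3. **Tracking models** — linear mixed models with random intercepts for
   country, study and child (4 levels with the residual), fitted by REML.
   Follow-up levels are regressed on baseline levels, both z-scored, so the
   coefficient *B* of the baseline term is a standardized tracking
   coefficient with Wald 95% CI: *no evidence* when p ≥ 0.05, otherwise
   low (|B| < 0.3), moderate (0.3–0.6) or high (> 0.6). Annual change in
   min/day/year comes from regressing the metric on time since baseline.
   Moderation by gender or age group (childhood: both ages ≤ 12; transition:
   baseline ≤ 12, follow-up > 12) is tested with interaction terms and
   stratified when p < 0.05.
4. **Synthetic cohorts** — a generator with exact, controllable ground truth
   (tracking correlation, annual drift, bout structure, non-wear blocks,
   spikes) so every stage is testable without access to restricted cohort
   data. Every realized quantity is recorded in a truth ledger.

## Worked example

Simulate a small cohort (2 countries × 2 studies × 25 children, 2 waves,
true standardized tracking 0.48, drift 21.4 min/day/year), process it and
fit the tracking models:

```sh
sedtrack all --config cfg.yaml --seed 3 --out-dir out/
```

with `cfg.yaml`:

```yaml
sim:
  n_countries: 2
  studies_per_country: 2
  children_per_study: 25
  waves: 2
  true_tracking: 0.48
tracking:
  metrics: [mean_total_sed, mean_prolonged_sed]
  moderators: [gender]
```

prints:

```
Tracking of sedentary accumulation metrics
============================================================

mean_total_sed
--------------
  annual change: 25.5 min/day/yr [20.6; 30.3]
  total sample:  0.55 [0.38; 0.72]  p=1.44e-10  moderate  (n=100)
  moderation by gender: interaction p=0.753

mean_prolonged_sed
------------------
  annual change: 24.4 min/day/yr [20.5; 28.3]
  total sample:  0.51 [0.33; 0.68]  p=1.98e-08  moderate  (n=100)
  moderation by gender: interaction p=0.0378
    boy          0.61 [0.38; 0.85]  p=3.29e-07  high  (n=45)
    girl         0.35 [0.11; 0.59]  p=0.00471  moderate  (n=55)
```

Reading this: daily total sedentary time rises by ≈ 25 min/day per year of
follow-up in this cohort (the configured truth, 21.4, lies inside the CI —
at 100 children sampling noise is substantial), and children keep their
population rank moderately (B ≈ 0.55 of an SD at follow-up per SD at
baseline, truth 0.48). The gender interaction for prolonged sedentary time
is a small-sample false positive (no gender difference was simulated) —
at this n such artefacts are expected; the stratified estimates still
bracket the truth. `out/` also contains the day summary (`days.csv`), wave
summary (`wave_summary.csv`), truth ledger (`truth.json`), results JSON,
and a run manifest with input checksums and attrition counts.

The same steps are available as library calls: `generate_cohort` /
`simulate_wave_summaries`, `run_process`, `run_track`, or the individual
operations (`detect_nonwear`, `prolonged_sedentary_time`,
`day_to_day_variation`, `fit_tracking`, ...).

## Limitations

Raw-acceleration processing, device binary formats (AGD/GT3X), non-wear
algorithms with tolerance windows, sleep detection and BMI reference
z-scores are out of scope. See `docs/methods.md` for the statistical model,
the generator's design and its known limitations.
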