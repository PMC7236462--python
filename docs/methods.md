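# Methods

## Data model and reduction rules

Epoch data arrive as one CSV row per epoch (`participant_id, study_id,
country_id, wave, timestamp, counts`), timestamps marking the epoch *start*
in local clock time. Within a calendar day epochs must be contiguous at the
declared resolution; gaps must be explicit missing rows (empty `counts`
field). This makes all downstream run-length logic unambiguous.

The reduction chain, in order:

1. **Reintegration.** Counts in sub-minute epochs are summed into 60-s
   blocks aligned to the clock grid. A block containing a missing epoch is
   missing; a partially covered block (possible only at stream edges) is
   treated as missing. A stream whose first timestamp is off the block grid
   is rejected rather than silently shifted.
2. **Spike invalidation.** 60-s epochs with counts strictly greater than
   30,000 cpm are marked invalid. Invalid minutes contribute to *no*
   category downstream: they are excluded from wear time, terminate
   zero-count runs, and are never sedentary. This is the most conservative
   reading of "non-valid".
3. **Waking window.** Only epochs starting in [07:00, 24:00) are kept:
   1020 minutes per day. Cropping precedes non-wear detection, so zeros
   before 07:00 can never extend a non-wear run.
4. **Non-wear.** Maximal runs of ≥ 60 consecutive zero-count minutes are
   non-wear, with no tolerance. Runs are evaluated within one day's window
   only. Missing and invalid minutes terminate runs.
5. **Valid day.** Worn minutes (window minutes that are neither non-wear
   nor invalid) ≥ 480. Weekend means Saturday or Sunday. For every day,
   worn + non-wear + invalid = 1020 by construction.
6. **Inclusion.** A participant is analysed when wave 1 (baseline) and at
   least one later wave each have ≥ 4 valid days including ≥ 1 *valid*
   weekend day. The first failing criterion is recorded as the exclusion
   reason. In an included participant, waves failing the rule are dropped
   from analysis; the participant is kept. Days with no recorded epochs are
   absent rather than counted as invalid days.

Intensity cut-points for worn minutes: sedentary < 100 cpm, MVPA
≥ 3000 cpm, light otherwise. Prolonged sedentary time sums maximal runs of
≥ 10 consecutive sedentary worn minutes; one non-sedentary, non-wear or
invalid minute breaks a run, and runs cannot bridge midnight because the
window ends there. Note an intended consequence of composing the two
printed rules literally: zero-count runs of 10–59 minutes are worn and
therefore *sedentary bouts*; only runs of ≥ 60 zeros become non-wear.

The day-to-day variation of a daily metric x₁…x_N over a wave is
Σᵢ|xᵢ − x̄| / N. N is the number of *valid* days contributing to that
wave's metrics (only valid days carry metric values; an alternative reading
— all worn days — is not implementable when metrics are undefined on
invalid days). The statistic returns exactly 0 on identical days.

## The multilevel tracking model

Observations are nested: repeated observations in children, children in
studies, studies in countries. Both analyses use linear mixed models with
random intercepts for country, study and child, REML estimation
(statsmodels `MixedLM`: the coarsest level as the grouping factor, the
finer levels as variance components), and Wald normal-approximation CIs and
p-values. Exact degrees-of-freedom corrections are out of scope; at the
sample sizes this package targets the normal approximation is adequate.

**Annual change.** metric ~ time_since_baseline + wear_time, all waves
included; the slope is the annual change in min/day per year. Wear time is
adjusted for because recorded wear mechanically scales every minute-count
metric.

**Tracking.** Outcome rows are the eligible follow-up waves (all of them,
one row each, when more than one exists); the baseline value enters as a
predictor and never as an outcome row. The predictor is z-scored by the
baseline sample's mean/SD (one value per participant), the outcome by the
pooled follow-up sample's mean/SD, both over the analysis sample; grand
rather than wave-specific standardization keeps a single interpretable
scale when follow-ups are pooled. The coefficient of the z-scored baseline
value is the standardized tracking coefficient. Covariates: outcome-wave
wear time *and* baseline wear time (each wave's wear distorts its own
metric), baseline age, gender, follow-up duration. Constant covariates
(e.g. gender inside a gender stratum) are dropped automatically.

Classification: *none* if p ≥ 0.05; otherwise by |B|: low < 0.3, moderate
in the closed interval [0.3, 0.6], high > 0.6. The magnitude is used
because a mixed model does not constrain B to [0, 1]; negative coefficients
are classified by size and keep their sign in the report.

**Moderation.** A baseline × moderator interaction is added (moderator
gender, or age group computed per participant from baseline age and the age
at the last eligible follow-up: childhood = both ≤ 12 y, transition =
baseline ≤ 12 < follow-up, adolescence = both > 12, the last excluded from
moderation analyses as a rare group). With a significant interaction
(p < 0.05) stratified models are fitted per level, the moderator dropped
from its own stratified covariate set (and baseline age dropped from the
age-group strata, which are themselves age-defined). For moderators with
more than two levels a joint Wald χ² is used.

**Degenerate designs.** A random level is collapsed, with a warning, when
it is unidentifiable: fewer than two units, no grouping beyond its parent
level, or one row per unit (the child intercept is confounded with the
residual in a 2-wave tracking fit, where each child contributes one outcome
row). If a fit is singular despite this, the finest remaining level is
collapsed and the fit retried; with every level collapsed the model *is*
OLS, which makes the degenerate-case equivalence with OLS exact rather than
optimizer-limited. Powell is tried before gradient optimizers: boundary
variance estimates (near-zero country/study variance is routine with a
handful of units) trip gradient-based convergence flags even when the
solution is correct.

## Synthetic cohort generator

The generator emulates a pooled multi-country children's accelerometry
design in three layers.

**Latent layer.** Child i's per-wave sedentary propensity (min/day) is

  P_iw = μ + c(country) + s(study) + δ·t_iw + B_iw,

with country and study offsets ~ N(0, σ_c²), N(0, σ_s²); drift δ in
min/day/year; t_iw the (jittered) years since baseline; and (B_i1,…,B_iW)
multivariate normal with SD σ_b and exchangeable cross-wave correlation ρ =
`true_tracking` (ρ = 1 handled as a shared draw). An analogous latent
governs prolonged sedentary time, clipped to ≤ total.

**Day layer.** Each wave's seven day targets (Monday–Sunday, so weekend
coverage always exercises the inclusion rule) are P_iw plus day noise of SD
σ_w that is *mean-centred within the wave*. The measured wave mean
therefore equals the latent propensity exactly, and the population
correlation of measured wave means equals ρ. This is deliberate: the truth
parameter is defined at the level of the quantity the tracking model
estimates, so parameter-recovery checks test the estimator itself rather
than a built-in errors-in-variables attenuation. Day-to-day variation
metrics are *derived* from the realized day targets — their tracking is not
separately controllable and is low by construction (day noise is
independent across waves), mirroring what such statistics do in real
cohorts.

**Epoch layer.** Each day becomes 1440 one-minute epochs: zeros from
midnight to 07:00; injected non-wear blocks (Poisson count per day, length
60 + Exp minutes) inside the window; the remaining worn time filled with
alternating sedentary bouts and active periods. The day's total-sedentary
and prolonged targets are apportioned across contiguous worn segments
(largest-remainder), so bouts never straddle a non-wear block. Within a
segment, ≥ 10-min bout lengths are 10 + truncated-geometric and < 10-min
bout lengths truncated-geometric (short bouts dominate, as they do in
children; ≥ 20-min bouts are rare); a degenerate `fixed` family makes every
bout one length. Sedentary counts are uniform on [0, 99]; active minutes
are lognormal light counts in [100, 3000) with MVPA bursts ≥ 3000 at a
configurable probability; spikes > 30,000 cpm are injected at `spike_rate`
per day. Two guards keep injected and detected non-wear identical when
spikes are disabled: worn zero minutes adjacent to an injected block are
bumped to [1, 99], and any incidental worn zero-run reaching 60 minutes has
its midpoint bumped (with uniform [0, 99] sedentary counts such runs are
already astronomically unlikely).

Realized quantities are recorded per day in the truth ledger by the
generator's own independent scan of the finished counts (zero-run, spike,
cut-point and bout rules re-applied directly), so ledger-versus-pipeline
comparisons cross two separate implementations of every rule.

**Guarantees and tolerances.** Realized total sedentary equals the rounded
day target exactly on every *feasible* day (target ≤ worn minutes after
non-wear injection); infeasible targets are clipped and the realized value
recorded. Realized prolonged time matches its target up to bout-feasibility
rounding (< 10 min targets rounded to 0 or 10 per segment) and is recorded
exactly; on very dense days (little active time to separate bouts) runs
merge and prolonged approaches total, which the ledger reflects.

**Default conditions.** 4 countries × 2 studies × 125 children = 1000
children (a desk-scale cohort preserving the multi-country, multi-study
shape), 2 waves 2.7 y apart (jitter SD 0.3 y), baseline ages uniform on
[5, 11.5] y so follow-ups span the childhood/transition boundary, true
tracking 0.48, drifts 21.4 (total) and 20.9 (prolonged) min/day/year,
baseline means 340 (total) and 150 (prolonged) min/day, between-child SDs
70/55, within-child day SDs 60/50, country/study SDs 10/15 min/day,
≈ 2.5 non-wear blocks/day of mean 95 min (wear ≈ 780 min/day), MVPA burst
probability 0.07 (≈ 25–30 MVPA min/day), spikes off. These echo the
magnitudes typical of pooled children's accelerometry. Epoch-level
realization is O(children × waves × 10,080) rows, so full-epoch runs in the
tests and acceptance script use 8–16 children; statistical checks use the
wave-summary fast path at 500–2000 children.

## What passing tests do and do not show

The generator's day structure is bout-alternating with independent day
noise; real accelerometer streams have autocorrelated behaviour, school-day
periodicity, seasonal effects and informative non-wear (removal correlated
with activity), none of which are modelled. Recovery of ρ and δ therefore
demonstrates correctness of the estimators under the stated model, not
robustness to those real-data features. Attrition is absent: simulated
children nearly always pass inclusion (wear ≈ 780 min/day), so inclusion
logic is exercised by dedicated hand-built fixtures instead.

## Numerical choices

- Boundary rules are exactly as stated: spike rule strictly >, 30,000
  retained; 60-zero run is non-wear, 59 is not; 480 worn minutes valid,
  479 not; minute at 07:00 kept, 06:59 discarded; 10-min bout counts,
  9 does not; classification interval [0.3, 0.6] closed on both ends;
  p = 0.05 exactly means "no evidence"; age 12.0 exactly is "≤ 12".
- Day-to-day variation returns exact 0 for identical days (short-circuits
  before floating-point summation).
- REML throughout; variance components bounded at 0; seeds mandatory for
  every stochastic path (`SimConfig.seed`, or an explicit seed argument).
- Missing counts are NaN internally, an empty CSV field on disk; the
  missing-data policy is "invalid minute" (contributes to no category).

## Known limitations

- Epoch gaps within a day are rejected rather than repaired; daylight-saving
  and timezone arithmetic are out of scope (local clock time only).
- The Wald/normal inference understates uncertainty in the country/study
  variance components when there are ≤ 5 units at a level; the tracking
  coefficient itself is insensitive to this at the tested sizes (empirical
  CI coverage 0.94–0.96).
- One bout-length family (truncated geometric) plus a degenerate `fixed`
  family; alternative bout definitions (≥ 5, ≥ 20, ≥ 30 min) are a config
  knob on `prolonged_sedentary_time`, not separately validated.
- `test_moderation` reports a single interaction estimate only for 2-level
  moderators; for > 2 levels it reports the largest interaction magnitude
  with a joint χ² p-value.
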