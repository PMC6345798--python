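# Methods

This note documents the models, conventions and design choices behind
`somnorate`: what the statistics assume, what the synthetic generators
emulate (and what they deliberately do not), and the numerical decisions a
user should know before trusting a result.

## Time and interval conventions

All times are seconds in double precision.  Every interval is half-open
`[start, end)`: a spike at `t` belongs to `[a, b)` iff `a <= t < b`, so
adjacent intervals partition time with no double counting.  Set operations
(intersection, subtraction, union) conserve time exactly:
`duration(a) = duration(a ∩ b) + duration(a \ b)` to 1e-9 s, which the test
suite checks against a 1-ms-grid membership oracle on randomized families.
Epoch thirds are built from shared bin edges so the three parts partition
the epoch exactly.

Rates are always `count / occupied_duration`.  Excluding a substate mask
therefore removes both the spikes and the time inside the mask; excluding
population-silent (OFF) time can only raise or keep any unit's rate — a
structural invariant the pipeline asserts.

## Epochs, sequences and controls

Only NREM epochs strictly longer than 150 s and REM epochs strictly longer
than 100 s enter any analysis (all wake epochs pass).  Epochs failing the
filter are invisible to pattern matching: they neither join nor break
sequences, but a rejected middle epoch does remove the triplet it would
have completed.

Sequence kinds and their default comparison periods:

| kind | period *i* | period *j* |
|---|---|---|
| state pairs (e.g. NREM→REM) | last third of first epoch | first third of second |
| within-state | first third | last third of same epoch |
| triplets (N-R-N, R-N-R) | last third of first flank | last third of second flank |
| first/last NREM of a sleep bout | last third of first NREM | last third of last NREM |
| wake–sleep–wake | last 60 s of the pre-sleep wake | first 60 s of the post-sleep wake |

A *sleep bout* is a maximal run of NREM/REM epochs; wake interruptions up
to `max_wake_interruption_s` (default 60 s, configurable — brief
arousals are part of sleep) do not break it.

The control period *k* for the shuffle null is the *corresponding* third of
the nearest same-state epoch that passes the filters and is not already
used by the sequence; by default it must lie in the same sleep bout
(overridable).  Sequences without a qualifying control are flagged excluded
rather than raising.  For wake-anchored comparisons, the control is a
uniformly random 60-s sub-interval of the same wake epoch (wake periods
separated by sleep differ systematically, so cross-epoch wake controls
would not be controls), reproducible under the run seed.  A sequence is
also excluded when more than 20% (strict) of principal cells fired zero
spikes in period *i* or *j* — the lowest quintile's change cannot be
measured in that case.  The 20% rule counts principal cells only, since it
exists to protect the pyramidal quintiles.

## Change index, surrogates, deflection index

The group CI is the change index of the group-mean rates,
`(mean_i − mean_j)/(mean_i + mean_j)`, over the group's cells, excluding
cells silent in both periods (their CI is undefined; the count is
reported).  Per-cell CIs are also computed: they back the antisymmetry /
boundedness / scale-invariance property tests and the per-cell signed-rank
summaries for interneurons.  Interneurons are never quintiled; they form
one separate group.

Quintile rule: the cell with ascending-rank `r` of `n` gets group
`ceil(5r/n)` (sizes differ by at most one; for n = 7 the sizes are
1,1,2,1,2).  Ties — including multiple zero-rate cells — break by
ascending unit id, making assignments reproducible.  Ranking uses either
the whole analysis window (for the descriptive quintile traces, which
avoids RTM by construction) or the period-*i* rates (for the CI/DI
analysis, which exposes RTM and is then shuffle-corrected).

Each of the 2000 surrogates independently swaps, with probability 1/2 per
cell, that cell's FRᵢ and FRₖ, re-derives quintiles from the post-swap
period-*i* rates, and computes the group CI *between the swapped pair* —
i.e. a within-state change, randomly time-reversed per cell, always
anchored at epoch *i*.  DI = observed CI − surrogate mean; the band is the
2.5–97.5 surrogate percentile range; the empirical two-tailed p uses +1
smoothing: `p = (1 + #{|s − m| ≥ |obs − m|})/(n + 1)`.  The flip
probability 1/2 is the exchangeability-preserving choice; a
fixed-membership surrogate (quintiles frozen at the observed assignment)
is deliberately *not* offered as a default because freezing membership
destroys the RTM reproduction that makes the correction work.

Known calibration property: the surrogate band is the flip-conditional
distribution of the within-state CI; it does not capture the full marginal
variability of a cross-state observed CI.  Under the pure-noise population
model the per-quintile 95% band is exceeded in roughly 13% (not 5%) of
simulated datasets.  DI point estimates and their cross-scenario
signatures are unaffected; band exceedance should be read as approximate,
and the suite documents the measured rate.  When several sequences are
pooled, the observed statistic is the across-sequence mean of per-sequence
group CIs and the surrogate distribution is the elementwise mean of
per-sequence surrogate vectors (independent flips per sequence), so bands
and p-values refer to the pooled statistic.

Multiple comparisons: none are enforced; raw empirical p-values are
reported with group counts.

## Substate detectors

* **OFF**: within each NREM interval, any gap of the pooled population
  spike train strictly longer than 75 ms, emitted as
  `(last_spike, next_spike)`.  Boundary gaps need flanking spikes inside
  the same interval, so state-transition silence is not counted.  No
  merging of near-adjacent gaps and no maximum duration are imposed.  With
  fewer than 10 units a warning is logged (population silence is then
  uninformative).
* **MA**: EMG power above `mean + 0.5·SD` (statistics over NREM samples
  only) — or above the valley of a bimodal EMG histogram — in maximal runs
  with duration strictly inside (0.1 s, 40 s).  No pre-smoothing is applied
  by default.
* **LOW**: band-power (nominally 0.625–50 Hz, 1-s windows at 0.1-s steps —
  the power series itself is an input) below a per-session threshold: the
  valley between the two largest modes of a smoothed histogram of log10
  power within NREM (100 bins, Gaussian kernel, sigma = 3 bins,
  deterministic).  Unimodal histograms fall back to the 10th percentile
  with a logged warning.

A sample at time `t` represents `[t, t + step)`, so a run of flagged
samples covers `[t_first, t_last + step)` and runs cannot span two NREM
intervals.

## Population simulator

The three-epoch simulator draws, per cell, a baseline rate from a
log-normal with *linear* mean 0.59 Hz and SD 0.84 Hz (the hippocampal-NREM
preset), converted by the exact moment match
`sigma² = ln(1 + sd²/mean²)`, `mu = ln(mean) − sigma²/2`.  Epoch rates are
`max(0, b·(1 + ε))` with ε ~ N(0, 0.35): multiplicative noise whose
absolute SD is proportional to the cell's rate (a 1-Hz cell has SD
0.35 Hz).  With this scale about 0.2% of rate values truncate at zero; the
truncated fraction is reported on every draw.  Epoch *j* optionally
carries an additive (+0.05 Hz) or multiplicative (×1.1) change; epochs *i*
and *k* stay at baseline — *k* plays the control period, and giving it the
change would make the null hypothesis test itself.

Closed-form signatures used by the tests: a ×1.1 change gives a uniform
cell-level CI of (1 − 1.1)/(1 + 1.1) = −1/21 ≈ −0.0476; a +0.05 Hz change
gives CI = −0.05/(2·FR + 0.05), strictly decreasing in magnitude with
rate.  Because single simulated datasets carry Monte-Carlo error, the
acceptance checks measure the mean DI profile over five independent
replicates and tolerate three standard errors of that mean.

## Session generator

`simulate_session` emulates the statistical structure the analysis
assumes, not the biophysics.  The hypnogram alternates wake and sleep
bouts of NREM–REM cycles (never wake→REM); epoch durations are log-normal
(defaults: NREM mean 600 s, REM 180 s, WAKE 900 s, CV 0.4 — conventions
chosen to resemble rodent sleep architecture, with configurable floors).
Spikes are piecewise-homogeneous Poisson: intensity = baseline ×
state-gain × substate gating.  Principal-cell state gains are per quintile
of baseline rate; the default REM profile (0.6, 0.8, 0.9, 1.0, 1.1) widens
the rate distribution in REM and the flat NREM profile narrows it on the
way back, with an interneuron REM gain of 1.3 and NREM gain of 0.8 —
the qualitative pattern the analysis is designed to detect.  Planted MA
and LOW intervals thin firing (default gain 0.5), elevate the EMG trace,
and depress the band-power trace respectively; both traces are generated
directly on a 0.1-s grid with interval bounds snapped to exact grid
multiples so detector recovery can be asserted to numerical precision.
Planted OFF intervals silence all units and are flanked by population
spikes exactly at their bounds, mimicking DOWN-state edge synchrony; this
makes the pooled-gap detector's output bit-comparable to the ledger.

Everything planted is returned in a ground-truth ledger (baselines,
quintiles, gains, substate intervals).  What the generator does *not*
emulate — and what passing tests therefore do not show about real data:
spike-sorting errors, non-Poisson discharge (bursting, refractoriness),
oscillatory phase locking, gradual within-epoch rate drifts, state-scoring
errors, and electrode drift.  Detector recovery on planted substates shows
the detectors implement their rules correctly, not that the rules are
sufficient for noisy recordings.

### Problem sizes used in the test suite

The planted-effect recovery experiments run 100 replicate sessions of 50
principal + 5 interneuron units and 22 NREM–REM cycles with scaled-down
epoch durations (NREM mean 300 s, REM mean 140 s, floors just above the
duration filters) — small enough to iterate quickly, and *harder* than
longer epochs, since shorter periods give noisier rate estimates.  The
OFF-recovery session instead uses a dense population (200 units, mean
3 Hz) so that a spontaneous pooled gap > 75 ms has negligible probability
and every detected OFF state is a planted one.  Population-simulator
checks run at the full 5000-cell scale.

## Pipeline

`run_transition_analysis` chains the stages per sequence kind and returns,
besides the pooled DI table, per-sequence ΔCV with a paired signed-rank
test, a pooled-rates KS comparison, and an accounting of sequences
excluded by each rule (duration filter, missing control, 20% rule) — these
exclusions materially change which cell-epochs enter the statistics, so
they are always reported.  `run_exclusion_variants` repeats the analysis
under substate-exclusion conditions and asserts the OFF-monotonicity
invariant.  All randomness derives from one seed via seed sequences
(per-kind, per-sequence streams); identical configuration and seed
reproduce reports byte-identically.

## Known limitations

Cell-epochs are treated as independent units, as in the underlying
analysis design; no mixed-effects modeling of the repeated use of the same
cells across sequences is attempted.  The surrogate band's anti-
conservatism under cross-state comparisons (above) means isolated
band-exceedances should not be over-read.  Δlog FR is provided for
comparison but excluded cells (zero rates) make it non-robust at low
rates, which is why CI is the default metric.
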