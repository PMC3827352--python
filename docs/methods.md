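# Methods

## Scope and data model

The package analyses trace-level data: each cell is a uniformly sampled
time series of the fura-2 excitation ratio *R(t) = F340/F380* (or the two
raw channels, divided samplewise), annotated with stimulus epochs.  ROI
extraction from image stacks, indicator calibration to absolute [Ca²⁺], and
multi-peak/oscillation decomposition are out of scope.  All quantities that
matter downstream are relative (percent over baseline, SD multiples), so
the absolute ratio scale is arbitrary; the generator uses baseline 1.0.

## Response quantification

**Baseline.** Mean and sample SD (n−1 denominator) of *R* over the
`baseline_window_s = 30 s` immediately preceding each epoch.  Each epoch is
scored against its own immediately-preceding window, so sequential stimuli
on one trace are independent provided the previous response has returned.
A zero SD (possible only for noise-free synthetic input) is replaced by an
epsilon floor so thresholds stay defined.

**Detection.** A cell is responsive when *R* exceeds `baseline + 2·SD` for
at least `min_run = 3` consecutive samples between stimulus onset and
`post_window_s = 60 s` after washout (responses may peak after the stimulus
is removed).  A bare single-sample 2-SD rule would fire on isolated noise
spikes; at the default operating point the run-of-3 rule keeps the
false-positive rate on pure-noise traces below 1 % (asserted in the test
suite over 10,000 traces) while detecting ≥ 99 % of responders whose
amplitude is at least five baseline noise SDs.

**Onset and offset.** Onset is the last sample at or below the baseline
mean before the qualifying run — the initial departure from baseline.
Offset is the first post-peak time from which *R* stays within
`baseline ± return_band_k·SD` (`return_band_k = 2`) for `return_run`
consecutive samples.  `return_run` trades two biases against each other:
a single-touch criterion (run 1) fires on transient noise dips while the
signal is still high (early bias), whereas long runs wait until the decaying
transient is deep inside the band (late bias — with run 5 the cohort mean
duration overshoots by ≈ 13 %).  A bias study on calibrated synthetic
cohorts (n = 300 per condition) measured mean duration errors of roughly
0 to +4 % for run 2, +5 to +7.5 % for run 3, and ≥ +10 % for run ≥ 4; the
default is `return_run = 3`, the smallest value robust to double noise
dips.  Responses that never re-enter the band before the recording ends are
flagged `excluded_no_return`; by default they keep their amplitude and
responsive status but are excluded from AUC and duration summaries (a
config switch extends the exclusion to all measures).

**Amplitude, AUC, duration.** Amplitude is `100·(peak − baseline)/baseline`
with the peak taken as the raw maximum of *R* over [onset, offset] (trace
end when no return).  No smoothing is applied by default; an optional
3-point moving average exists but alters amplitudes and is documented as
such.  AUC is the trapezoidal integral of `max(R − baseline, 0)` over
[onset, offset] — negative excursions contribute nothing.  Duration is
offset − onset.

## Cell typing and umami gating

Cells responding to 50 mM KCl (same 2-SD rule; no separate criterion is
defined for the depolarising control) are presumptive Type III; KCl-tested
non-responders are presumptive Type II; cells without a KCl epoch are
undetermined and — conservatively — excluded from umami analysis rather
than assumed Type II.  MPG responses count as umami responses only in
KCl-negative cells, because MPG's potassium can depolarise Type III cells
directly; responder tables and property comparisons for MPG are built from
that gated subset.

## Cohort statistics

Responder frequencies: Pearson chi-square on cohort × (responsive,
non-responsive) tables via `scipy.stats.chi2_contingency`, without Yates
continuity correction by default (flag available).  Group-vs-control bar
comparisons use pairwise 2×2 tables without family-wise adjustment,
matching per-bar significance marks; the omnibus 2×k test is also computed.
Response properties: one-way ANOVA (`scipy.stats.f_oneway`) over evoked
responses only, with pairwise pooled-variance Student t-tests multiplied by
the number of pairs (Bonferroni, one family per stimulus × measure; Welch
available behind a flag).  Degenerate t-tests (zero variance in both groups,
equal means) return p = 1 by convention, logged.  Cells are treated as
independent observations — within-animal correlation is not modelled, a
known limitation.  Significance at p < 0.05 (*, **, *** at 0.05/0.01/0.001).

## Two-bottle preference analysis

Each concentration is offered against water for 48 h with a 24 h side swap.
The preference ratio pools volumes: `Σ test / Σ (test + water)` over both
periods — pooling, not averaging daily ratios, is what makes a pure side
preference cancel (verified as a property test with side-biased synthetic
drinkers).  Concentration series are analysed with a mixed repeated-measures
ANOVA (`pingouin.mixed_anova`; between = diet group, within =
concentration; Greenhouse–Geisser correction off by default, flag
available) with Bonferroni-adjusted per-concentration contrasts, plus a
second tier of unadjusted per-concentration Student t-tests.

## Synthetic-data generator

The generator emulates the study conditions so every stage is testable
without external recordings.

**Transient model.** Responders get an additive bump on a flat baseline: a
saturating exponential rise reaching the peak exactly `3·rise_tau` after
transient onset (normalised, and grid-snapped, so the configured peak
appears exactly in the sampled trace), then a pure exponential decay with
time constant `decay_tau`.  The pure-exponential tail makes duration
calibration closed-form: the noise-free transient re-enters the band
`baseline ± k·noise_sd` at `t_peak + decay_tau·ln(peakΔ/(k·noise_sd))`
after onset, inverted by `calibrate_decay`; `calibrate_auc` analogously
solves for the decay constant whose onset-to-band-re-entry positive-part
integral matches a target AUC.  Non-responders are baseline plus i.i.d.
Gaussian noise (an optional linear drift term exists for stress-testing
baseline estimation and is off by default).

**Operating point.** Sampling interval 1 s (unstated in the source
protocol; typical for fura-2 ratio imaging and sufficient for 50–65 s
responses).  Stimulus epochs 30 s long starting at t = 30 s; transient
onset latency 2 s; rise_tau 2 s (peak 6 s after onset); default decay_tau
12 s.  Baseline noise SD 0.002 ratio units (0.2 % of baseline): within the
range of clean ROI-averaged fura-2 ratios, and deliberately at the clean
end — the peak estimator is a maximum over a window and the offset
estimator is a threshold crossing, and the operating point was chosen (via
the same bias study as `return_run`) so these estimators' noise-induced
biases stay small relative to the biological dispersion the generator
models.  Passing recovery tests at this operating point demonstrates
pipeline correctness and calibration; noisier real recordings would inflate
peak amplitudes and delay offsets, which is why those estimator biases are
documented here rather than hidden.

**Cohort dispersion.** Per-cell amplitudes are drawn as
Normal(preset mean, CV·mean) truncated at 5 % of the mean, CV = 0.25 —
group means in this literature come with substantial SEM bars, so
cell-to-cell dispersion is part of the conditions, and it (not measurement
noise) dominates the standard error of recovered cohort means.  Per-cell
randomness uses `SeedSequence(master, spawn_key=(cell,))` substreams, so a
cell's trace is identical regardless of cohort size.

**Calibrated presets.** Amplitude presets carry the published group means
(% over baseline): MPG 18.6/15.7/17.0, SAC 74.2/19.1/8.2, AceK
37.8/21.1/7.9, Den 59.8/12.4/22.1 for control/obese-male/obese-female.
Denatonium duration presets calibrate `decay_tau` to 50.5 s (control) and
65.5 s (obese pooled; its amplitude is the n-weighted mean of the sex
-specific means, 15.4 %).  The control-AceK preset calibrates `decay_tau`
to the published AUC mean of 29.2 ratio·s.  Responder fractions are *not*
numerically published (bar graphs only); the preset fractions are free
parameters chosen once in the reported ordering (sweet responsiveness
strongly reduced in obese cohorts, umami/bitter unchanged) and documented
as such.  Trace lengths are set per preset so that even a +5-CV amplitude
draw returns to baseline before the recording ends — otherwise no-return
exclusions would bias AUC/duration summaries.

**Intake generator.** Per animal × concentration × 24 h period, total
intake is Normal(6 mL, 1 mL) truncated at zero, split between the test
bottle and water with expected test share equal to the configured true
preference; animal-level variation follows a Beta distribution with
concentration κ = 50, and an optional side-bias term shifts each period's
share toward the animal's preferred side (cancelled by the 24 h swap).
Concentration series follow the behavioural protocol (e.g. AceK 1, 2, 20,
50 mM; saccharin 1, 2, 10, 20 mM; MPG 10, 30, 100, 300 mM; denatonium 0.1,
0.5, 1, 10 mM; sucrose 5, 50, 150, 300 mM).

**What the generator does not model.** Photobleaching, motion artifacts,
multi-peak or oscillatory responses, correlated (non-white) noise,
within-animal correlation of cells, circadian intake structure, and
post-ingestive feedback on intake.  Passing recovery tests therefore shows
the pipeline is correct and calibrated under these idealised conditions,
not that it is robust to every artifact of real recordings.

## Problem sizes

Recovery summaries use 500-cell cohorts per preset (standard errors of
cohort means ≈ 1 % of the mean at CV 0.25); detection specificity uses
10,000 noise-only traces; statistical-stage calibrations use 1,000 null
replicates.  These sizes put Monte-Carlo error well below every tolerance
used in the tests while keeping the full suite fast.

## Known limitations

- The 2-SD rule's specificity and the offset estimator's bias are functions
  of the noise level; on noisier data the configurable `min_run`,
  `return_band_k` and `return_run` should be re-examined.
- Whether non-returning responses should be excluded from *all* summaries
  or only AUC/duration is ambiguous in the source protocol; the default
  excludes them from AUC/duration only, behind a config switch.
- Cell-level independence is assumed throughout the cohort statistics.
- The mixed ANOVA reports the uncorrected univariate within-subject test by
  default; enable the sphericity correction for series with strong
  covariance structure.
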