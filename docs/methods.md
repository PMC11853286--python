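# Methods

## Scope and data model

The pipeline starts from per-cell fluorescence traces exported after ROI
extraction (time × cell, nominally 20 Hz), a GPIO table carrying the
experiment-start trigger, a START/STOP behavioral event log, and an
experiment schedule. ROI extraction itself (motion correction, PCA-ICA,
manual cell acceptance) is upstream and out of scope; demonstrator
behavior and video scoring are likewise consumed, not produced.

Time is in seconds with 0 at the GPIO trigger. Every window is half-open
`[start, end)`, so an event on a shared boundary is counted exactly once.
Samples recorded before the trigger are discarded rather than kept at
negative time: nothing downstream can use them, and discarding keeps every
container's invariant simple (`times[0] ≥ 0`).

## Schedule

`generate_schedule` draws inter-trial intervals (shock offset → next
onset) uniformly from 30–60 s, places shock k at
`habituation + Σ_{i≤k} ITI_i + (k−1)·shock_duration`, and attaches LED
windows `[onset − 1, onset + shock_duration + 1)` to the ON trials. With
20 shocks the OFF/ON split is trials 1–10 / 11–20; for other counts the
first ⌈n/2⌉ trials are OFF. The mean shock phase is ≈ 940 s, consistent
with a 15-minute shock period after the 5-minute habituation. A
configurable `tail` (default 60 s) of recording follows the last shock so
that late events have somewhere to fall.

## Transient detection

The detector implements a thresholding rule, not model-based
deconvolution: an event is a strict local maximum above
`baseline_mean + k·baseline_sd`, k = 2 by default.

* **Baseline.** Default is the mean/SD of the whole trace; a
  `habituation` option restricts the estimate to the first 300 s. Both
  are reasonable operationalizations of a "baseline" for a mostly
  quiescent session, and they differ when shock responses are large and
  frequent (the whole-trace SD is then inflated and the detector more
  conservative). The SD is the sample (n−1) estimate — immaterial at
  24,000 samples, fixed for reproducibility.
* **One event per excursion.** A contiguous supra-threshold excursion
  yields a single event at its maximum sample, so one slow GCaMP6f
  transient cannot register as many "spikes". Remaining peaks closer than
  `min_separation` (default 0.25 s, i.e. 5 frames at 20 Hz) are merged
  onto the larger peak.
* **Edge conventions.** Exceedance is strict (a maximum exactly at
  threshold does not fire). NaN samples (dropped frames) are excluded
  from the baseline and can never be peaks. Detection is invariant to
  adding a constant to the trace and to positive rescaling, because the
  threshold moves with the baseline statistics.
* **Timestamp lag.** The event timestamp is the peak sample, which lags
  the underlying calcium event by the kernel rise (≈ 0.17 s for the
  synthetic defaults). A baseline event ending up just before a window
  boundary can therefore be timestamped just inside it; this is a
  property of peak-timestamping itself and is visible in the end-to-end
  recovery numbers (below).

## Shuffle-null classification

For one condition (OFF or ON), the statistic is the mean event rate over
the union of that condition's 2-s shock windows. The null is built by
circularly shifting the cell's entire event train by Δ drawn uniformly
from 20–1200 s, wrapping modulo the session length, and recomputing the
statistic; 1000 independent shifts by default. Wrapping (rather than
truncating) conserves the event count and the train's circular
inter-event intervals, so the null holds each cell's overall rate and
burstiness fixed while destroying alignment with the schedule;
non-wrapping shifts would push events off the end of the session and bias
null rates downward. Percentiles use numpy's linear interpolation between
order statistics.

Calls, all strict inequalities:

* SRC: observed OFF rate > 95th percentile of the OFF null.
* SSC: observed OFF rate < 5th percentile of the OFF null.
* Suppressed (evaluated only for SRCs): the ON-condition rate fails the
  same test against a fresh null computed over the ON windows.
* ON-only SRC: not an SRC, but the ON-condition rate exceeds its null's
  95th percentile.

The ON test uses the 2-s shock windows of the ON trials — the statistic
is the rate "during the shock moment" — with the 4-s LED windows
available as an option. An empty train is never significant in either
direction (its observed rate and entire null are 0, and the inequalities
are strict). Cells from different sessions are independent sets; no
cross-session matching and no multiple-testing correction across cells is
applied — calls are raw per-cell 5%-level tests, and the session summary
reports counts of such calls.

With ~120 events per null cell the windowed counts are small integers, so
the empirical 95th percentile often ties achievable values; the strict
inequality then makes the realized type-I rate hover at or slightly below
the nominal 5%. The calibration test (400 homogeneous-Poisson cells)
checks the call fraction against the 95% binomial band around 0.05.

## Behavior metrics

Freezing epochs are paired START/STOP records; abutting records (gap = 0)
are merged before filtering, so splitting one bout into two records
cannot change the result. An accepted bout lasts strictly more than 2 s.
A bout belongs to the period in which it begins, with its full duration
credited there (no clipping at the period boundary; a `clip_to_period`
option exists). The OFF comparison period runs from the first OFF shock
onset to the first LED onset, and ON from the first LED onset to session
end; the protocol itself does not define these periods, so they are
explicit, documented defaults and configurable. The shock-onset metric
averages the durations of bouts beginning inside a 2-s shock window of
the period. When a period contains no bouts the mean is reported as 0
with `mean_defined = False`.

## Statistics

The suppression split (suppressed vs not, among SRCs) is tested with a
two-sided chi-square goodness of fit against equal proportions, *without*
continuity correction — on a 26/1 split this gives X² = 23.148, df = 1
(Yates' correction would give 21.3; the uncorrected form is the
convention used throughout). Behavioral OFF/ON comparisons use two-tailed
paired t-tests with df = n_sessions − 1; zero-variance differences are
flagged undefined rather than reported as infinite t. p-values print to 4
decimals, with "< 0.0001" below that. Percentages in summaries are
recomputed from their own counts and rounded to one decimal — a 26/27
split is reported as 96.3%.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes,
from one master seed (identical seed ⇒ bit-identical files):

* **Event trains** are inhomogeneous Poisson processes, piecewise
  constant: a cell's rate switches from its baseline to a class-specific
  rate inside shock windows. Defaults: baseline 0.1 events/s (sparse
  GCaMP6f-like event rates), responder shock-window rate 2.0 events/s
  (20× baseline — a strong, clearly recoverable effect), SSC baseline
  0.5 events/s with ~0 in shock windows (suppression is only detectable
  against a non-trivial baseline: the 5th-percentile criterion needs the
  null to be positive). Rates are configurable for effect-size sweeps.
* **Traces** convolve the train with a difference-of-exponentials kernel
  (rise 0.08 s, decay 0.5 s, unit peak) on the 20 Hz grid, plus baseline
  level and Gaussian noise at amplitude/6 — comfortably above the 2-SD
  rule for isolated events. Only the kernel's qualitative shape matters.
* **GPIO** rises at a configurable offset (default 5 s) after acquisition
  start, so alignment is exercised, and the trace grid covers the offset
  plus the session.
* **Behavior** is a two-state alternating renewal process (exponential
  move/freeze durations, means 20 s / 6 s) with probability 0.5 of an
  extra freeze bout starting inside each shock window. It exercises the
  metrics code; it does not model real freezing dynamics.

What the synthetic data does **not** reproduce: correlated noise and
neuropil contamination, photobleaching drift, burst/refractory event
statistics, motion artifacts, or realistic freezing autocorrelation.
Passing tests therefore demonstrate correctness of the computations and
calibration under the stated generative assumptions, not performance on
arbitrary real recordings.

## Recovery and calibration experiments

The recovery experiment plants 10 SRC_SUPPRESSED, 5 SRC_NOT_SUPPRESSED,
5 SRC_ON_ONLY, 5 SSC and 40 NULL cells in one session. Per-class
sensitivity is the fraction of planted cells whose defining flag is set
(e.g. SRC_SUPPRESSED ⇒ `is_src` and `suppressed`); NULL specificity is
the fraction of NULL cells called neither SRC nor SSC in the primary
OFF-condition test (the exploratory ON-only flag, a second 5%-level test,
is tallied separately). The test-suite experiment classifies the planted
event trains — it isolates the classifier, whose detection-free
sensitivity is the quantity of interest; the acceptance script reports
both that and the full trace→detection→classification path, where SSC
sensitivity can dip because of the peak-timestamp lag noted above.

Problem sizes are chosen so the full suite runs in seconds: 400 null
cells × 200 shuffles for calibration (200 shuffles give the 95th
percentile from 10 exceeding order statistics — coarse but unbiased for a
band check), 1000 shuffles everywhere a single cell's call matters.

## Pipeline and reproducibility

`run_pipeline(config, out_dir, seed)` orchestrates
simulate/load → align → detect → classify → behavior → statistics.
The YAML/dict config has one input source — `simulate` (cell-class map
plus generator knobs) or `inputs` (file paths) — and optional `detection`
(`baseline_method`, `sd_multiplier`, `min_separation`), `classification`
(`n_shuffles`, `shift_range`, `conditions`, `use_led_windows`) and
`behavior` (`min_bout_duration`, `clip_to_period`) blocks. Every stage
failure is re-raised naming the stage. A manifest (config hash, master
seed, package version, output list) accompanies the reports, and repeated
runs under one master seed are byte-identical.

## Known limitations

* The 2-SD peak rule is deliberately simple; with whole-trace baselines
  and dense activity its threshold inflates, and with noisy traces it
  admits false events at a rate set by the noise tail. It is not a
  substitute for spike inference when event times matter at < 100 ms
  resolution.
* The shuffle test is per-cell and uncorrected; with hundreds of cells,
  ~5% of nulls will be called in each direction by construction.
* SSC detection requires a baseline rate high enough that the null's 5th
  percentile is positive (roughly > 0.15 events/s over 20 s of windows);
  truly silent cells cannot be called suppressed.
* Behavioral comparisons across sessions treat sessions as exchangeable
  pairs; session-level covariates (mouse identity, order) are not
  modeled.
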