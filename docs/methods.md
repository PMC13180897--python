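# Methods

## The task program

The stimulus program is a 16-trial movie in four blocked conditions —
word, reverse Stroop, color, Stroop — four trials each.  A trial presents
a center stimulus and four answer options, one per corner; exactly one is
correct.  Trials last 7 s with a 1-s inter-trial interval, and a 2-s
instruction slide separates blocks.  Within each condition the four
correct colors are a permutation of the four-color palette, so no color
repeats as the answer inside a block.

Two choices in the generator go beyond what the task description fixes and
are this package's own:

* **Condition semantics.** The matching format is implemented as: *word* —
  a neutral-ink color word with patch options (answer = meaning); *reverse
  Stroop* — an incongruently inked color word with patch options (answer =
  meaning, ink must be suppressed); *color* — a patch with word options
  (answer = the naming word); *Stroop* — an incongruently inked color word
  with patch options (answer = ink, meaning must be suppressed).  This is
  the standard matching-type Stroop arrangement; only the four condition
  names are fixed by the task description.
* **Corner balance.** The correct corner is a seeded permutation of the
  four corners per condition (a Latin-square balance), so each corner is
  correct exactly four times over the 16 trials and spatial gaze biases
  cannot masquerade as accuracy.  Whether the original instrument balances
  corners is unknown; balancing is the conservative choice for a scoring
  engine.

The default palette is red/blue/green/yellow (configurable); block order
defaults to word → reverse Stroop → color → Stroop.  Coordinates are
normalized screen units, origin top-left, y downward.

## Scoring

Gaze recordings are timestamped `(t, x, y, valid)` streams at a nominal
50 Hz.  Trial windows are **half-open** `[onset, onset + 7)`: a sample on
a boundary belongs to the next interval, so windows partition trial-time
samples with no double counting.  The clock alignment between recording
and schedule is an explicit offset parameter, default 0.

The trial score is `100 · n_hit / n_valid`: the share of *tracked* time
spent in the correct-option ROI.  Design choices:

* **Denominator.** "Percentage of viewing time" is read as a share of
  tracked time, so invalid (track-lost) samples are excluded from the
  denominator.  A `denominator="window"` option uses the full 350-sample
  budget instead for sensitivity analyses.
* **ROI geometry.** Each corner ROI is a 0.4 × 0.4 screen-fraction
  rectangle anchored in its corner, with half-open containment so ROIs are
  pairwise disjoint even at 0.5 fraction.  The real instrument's ROI
  dimensions are not published; 0.4 leaves a neutral central band around
  the instruction stimulus.
* **Quality control.** A trial passes QC when at least 50% of its expected
  samples are valid; failing or empty trials are dropped from the means
  (not imputed as 0, which would conflate tracking failure with
  impairment), and a participant is flagged unusable when more than 8 of
  16 trials fail.  These thresholds are the package's own; no data-quality
  rules are published for the original instrument.

Condition scores average each condition's scored trials; the total score
averages all scored trials.  Both live in [0, 100].

## Clinical cutoffs

MMSE 28–30 → cognitively normal, 24–27 → suspected MCI, ≤23 → suspected
dementia; FAB ≤11/18 → frontal lobe dysfunction; CDR 0 / 0.5 / ≥1 →
CN / MCI / dementia.  TMT cutoffs are configuration-required because the
published values are age-normed and cited rather than printed; the
working defaults (A: 90 s, B: 180 s, abnormal strictly above) must be
reviewed for any real cohort.  The paper-based Stroop total is the sum of
the four 40-s condition counts — the only monotone aggregation consistent
with a "total score" of counts.

## Validation statistics

* **Spearman** uses midranks for ties and the two-sided t-approximation
  (delegated to `scipy.stats.spearmanr`), with pairwise deletion of
  missing values and a flag instead of an exception for constant input.
* **Mann–Whitney U** is `Σ 1[a > b] + ½·1[a == b]`.  For n₁+n₂ ≤ 12 the
  two-sided p is exact by full enumeration of the C(n₁+n₂, n₁) group
  relabelings — valid under ties, where the classical exact tables are
  not — with the convention `p = min(1, 2·min(P(U ≤ u), P(U ≥ u)))`.
  Larger samples use the tie-corrected normal approximation with
  continuity correction.
* **ROC/AUC**: the curve is computed over all thresholds and the AUC by
  trapezoid, which equals the pairwise estimator U/(n₁·n₂) exactly (an
  identity the test suite asserts to 1e-12).  Scores are oriented by an
  explicit `direction` argument (lower dwell percentage = impaired), so
  informative scores give AUC ≥ 0.5.  The 95% CI defaults to DeLong's
  placement-value variance — the standard choice when the CI method is
  otherwise unspecified — clipped to [0, 1]; a seeded stratified bootstrap
  (2,000 resamples, percentile interval) is available and is the automatic
  fallback when the DeLong variance degenerates to zero (e.g. perfect
  separation).
* All tests are two-sided at α = 0.05.  Each result reports the n used
  after per-analysis deletion, since instrument availability varies
  (TMT discontinuation in particular).

## The synthetic cohort model

No participant-level data are available for this instrument, so the
pipeline is exercised on a generative model whose parameters are explicit
and whose qualitative structure — not its exact effect magnitudes — is the
validation target.

Each participant has latent frontal function φ and global cognition g,
bivariate standard normal with correlation ρ = 0.6.  Instrument scores are
noisy affine transforms anchored to typical memory-clinic moments (MMSE
24.1 ± 4.4, FAB 12.4 ± 3.0, age 76.4 ± 7.1, TMT-A ≈ 77 s, TMT-B ≈ 153 s,
97 participants), clamped to instrument ranges; paper-Stroop counts are
Poisson with log-rate increasing in φ and decreased by the condition's
interference penalty; TMT values go missing with probability increasing as
φ falls, mimicking discontinuation (≈12% for part A, ≈27% for part B at
the defaults); FAB is missing completely at random at ≈3%.

Gaze in a trial is two-phase:

1. **Search**: duration `T_s ~ LogNormal(μ₀ − 0.3·φ + 0.2·penalty, 0.5)`
   with μ₀ = log 2 (median 2 s), censored at the 7-s trial length.  Gaze
   hops among five regions — the screen center and the four option ROIs —
   with geometric hop lengths (mean 0.25 s) and uniformly chosen targets,
   so each region's expected occupancy share is exactly 1/5.
2. **Decision**: the participant picks the correct option with probability
   `logistic(β·φ − penalty(condition))`, β = 1.5, penalties 0 / 0 / 0.5 /
   1.0 logits for word / color / reverse-Stroop / Stroop; each decision
   sample sits on the chosen option with probability p_stay = 0.9, else on
   one of the other four regions uniformly.

Samples drop out independently at a 5% track-loss rate.  Because loss is
independent of position, it cancels from the tracked-time percentage, and
the expected trial score has the closed form

    E[pct] = 100·[ s̄/5 + (1 − s̄)·( q·p_stay + (1 − q)(1 − p_stay)/4 ) ]

with `s̄ = E[min(T_s, 7)]/7` (capped-lognormal mean, closed form) and
`q = logistic(β·φ − penalty)`.  This expression is the simulator's
calibration oracle: Monte-Carlo means are required to match it within 3
points of percentage over a φ × condition grid.

What the simulator does **not** emulate: saccade kinematics and fixation
microstructure, blink bursts (loss is i.i.d., not bursty), head motion,
calibration drift, learning or fatigue across trials, and education or
age effects on the latents (age is correlated with g only weakly).
Passing tests therefore demonstrate that the engine recovers the
statistical structure a cohort of this shape produces — positive
eye-tracking/paper/FAB/MMSE correlations, negative TMT correlations,
above-chance dysfunction AUCs, interference ordering of condition means —
not that any particular published effect size would be reproduced on real
patients.  With the default effect sizes the synthetic correlations and
AUCs come out stronger than is typical of real clinical data, since the
model has no unmodelled between-participant heterogeneity beyond the two
latents.

## Numerical conventions

Half-open interval and rectangle containment everywhere (no double
counting at boundaries); NaN marks missing scores and is never silently
treated as 0; means over empty sets are NaN, and analyses that would be
degenerate (constant score, a missing group) are reported as missing
entries rather than dropped.  All simulation randomness flows from one
master seed through per-participant spawned substreams, so cohorts are
reproducible and participant k does not depend on how many participants
follow it.  Problem sizes in the test suite (e.g. 10,000 trials per
calibration cell, 100 seeds for direction recovery, 60–97 participants
per simulated cohort) were chosen to keep Monte-Carlo error well inside
the asserted tolerances.
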