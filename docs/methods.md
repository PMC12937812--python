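# Methods

## The simulated study

One session comprises six runs at TR = 2 s in the fixed order tapping,
tapping, imagery, imagery, tapping, tapping. Tapping runs alternate six
blocks of paced tapping (speeds alternating 1 Hz / 4 Hz) with six rest
blocks; imagery runs open with two practice blocks (one noITAP-like,
one ITAP-like) followed by six alternating ITAP/noITAP blocks. Block
durations are drawn uniformly from {28, 30, 32} s, i.e. whole TRs, so a
run's volume count is exactly its schedule duration over TR (≈170–190
volumes for tapping runs). Runs 1–2 train the decoder, runs 3–4 replay
closed-loop neurofeedback, runs 5–6 are the held-out positive control
and the post-intervention behavioral measurement.

## Signal model

Each voxel's time course is

    y(t) = baseline + a_c · (boxcar_c ⊛ h)(t) · 1[motor voxel]
         + drift · t + m(t)ᵀ λ + ε(t)

with `h` the canonical double-gamma HRF (response delay 6 s, undershoot
delay 16 s, dispersions 1 s, peak:undershoot 6:1, 32 s support,
normalized to unit continuous-time peak so amplitudes are in signal
units), `boxcar_c` the indicator of condition c sampled at the TR,
`m(t)` six slow random-walk motion series with per-voxel loadings λ,
and ε white Gaussian noise (an AR(1) flag exists, default off, since
the analysis GLM assumes no particular autocorrelation). Convolution is
done on the TR grid; block onsets are whole TRs, so no finer grid is
needed.

The planted "motor network" is three 3×3×3 blobs (80 voxels after mask
intersection) inside the analysis mask of a 16×16×10 ellipsoidal brain
— a desk-scale stand-in for a 64×64×39 acquisition that preserves the
temporal structure while shrinking space. The visual-exclusion mask is
a posterior slab, resampled from a 2× finer source grid with the ≥20%
voxel-occupancy rule; the analysis mask is brain AND NOT visual.

Key defaults and why:

- `tap_amplitude = 2`, `noise_sd = 6` (per-voxel, per-TR CNR ≈ 0.33).
  Single-voxel, single-TR BOLD is noisy; decoding works by pooling over
  blocks and voxels. This operating point also keeps the training data
  non-separable, so the soft-margin SVM (C = 100, the common default of
  real-time SVM tooling) spreads weight over informative voxels rather
  than collapsing onto a hard-margin solution dominated by noise
  dimensions. At this preset the held-out accuracy averages ≈0.91 and
  the top-decile |w| Dice against the planted network ≈0.55 over seeds.
- Imagery amplitude ~N(1.2, 0.4²) clipped positive: covert imagery
  activates the motor system more weakly than overt tapping (how much
  more weakly is not established, so it is a config parameter); this
  yields imagery feedback accuracies in the high 50s–60s %, i.e.
  modestly above chance, as observed in patient studies.
- Tap streams: taps at nominal 1/rate spacing with Gaussian timing
  jitter; jitter SD is set from a per-run RMSE target via
  RMSE ≈ rate² · σ · √2 (first-order expansion of 1/Δt). Run-level
  RMSE targets mirror a mildly impaired population (≈0.02–0.04 Hz at
  1 Hz, ≈0.06 Hz at 4 Hz). `miss_prob = 0.001`: misses are rare events,
  and a single miss at 1 Hz adds ≈0.05 Hz in quadrature to a run RMSE,
  which would drown the ≈0.01 Hz improvement signal the study tracks.
- Cohort coupling: per subject, standardized draws (z₁, z₂) give
  imagery amplitude ∝ z₁ and a 1 Hz ΔRMSE built from
  ρ·z₁ + √(1−ρ²)·z₂, so the population correlation between planted
  activation and improvement equals the requested coupling ρ. An
  ICARS-like severity covariate (N(32.4, 19.2²), clipped to [0, 100])
  is drawn independently.

## Preprocessing and decoding

Offline (training) preprocessing regresses intercept, linear trend and
the six motion series out of each voxel, then smooths spatially
(Gaussian, 1.7-voxel FWHM ≈ 6 mm at 3.5 mm voxels). Slice-timing
correction is a deliberate no-op: synthetic volumes have no slice
offsets, and interpolation for real data belongs upstream.

Online preprocessing estimates the same nuisance coefficients on the
volumes acquired *before* the incoming one within the same run, then
subtracts their prediction at the new time point; with fewer than 8
volumes of history the volume is only centered on the history mean.
The leading practice blocks exist exactly to build up this history.

A plain history-only fit systematically absorbs task signal: the
extrapolated trend tracks the current block's elevation, and the
decision margin decays toward zero late in every block, capping
held-out accuracy around 75% regardless of CNR. The fix used here —
and the package's main design choice in this module — is to include
the known task regressor (the display schedule, which the feedback
computer has by construction) in the history fit as a *protection*
column that is never subtracted from the volume. Nuisance estimates
then stay clean while the task response passes through to the decoder.
Training preprocessing mirrors this (nuisance-only subtraction with a
task-protected fit) so the feature distributions match between
training and replay. When no task regressor is passed, both functions
reduce to the plain projection.

Labels for training and held-out evaluation are the schedule conditions
shifted by 2 TRs (≈4 s hemodynamic delay); the first two volumes of a
run are unlabeled. Decoding is `w·x + b` over analysis-mask voxels with
ties (exactly 0) decoded as rest. Note a structural limit checked by
the tests: because the BOLD ramp at a block boundary spans ~1 TR either
side of the shifted label, even a noiseless session decodes at ≈93%,
not 100%; exact-100% oracle properties are asserted at the state-machine
level where the decoder truly is an oracle.

## Feedback scoring

The display at TR t is driven by the decode of volume t − latency
(default 2 TRs). Practice TRs always show the ideal pattern and are
unscored; TRs whose delayed decode does not exist yet are likewise
unscored (with practice blocks leading, none of the scored ITAP/noITAP
TRs lose their decode). Scored TRs whose delayed decode originates in
the previous block are scored against the condition of the TR being
*displayed* — the scoring asks what the display did at each TR. No
hemodynamic shift is applied to scoring labels; that shift belongs to
training, not to display bookkeeping.

## GLM analysis

First-level designs contain HRF-convolved task columns (block boxcars
for tapping; 1-TR sticks for the event-related imagery design, where
"successful imagery" events are the true-ITAP TRs of the feedback trace
and all other scored imagery TRs form the comparison regressor), an
intercept, polynomial drift, and the motion series as unconvolved
confounds. Rank-deficient designs (e.g. an all-zero event column) are
rejected with the offending columns named. Fits are per-voxel OLS; the
imagery contrast is [1, −1] between the two event regressors, averaged
over runs 3–4, on data smoothed at 2 voxels FWHM (the 8 mm-equivalent
group-analysis kernel; a 4 mm-equivalent preset exists for small-lobule
work).

Group maps: voxelwise one-sample t (df = n−1; zero-variance voxels are
NaN, never ±∞) and the covariate model regressing subject contrasts on
[intercept, ΔRMSE, control] with the ΔRMSE coefficient's t (df = n−3).
A constant control covariate is dropped (reducing to the two-column
fit, df = n−2); genuinely collinear covariates are rejected.
Thresholding is one-sided positive by default (activation maps; signed
covariate tables come from running each direction), configurable
two-sided; clusters form under face (6-neighbor) connectivity — chosen
over the larger neighborhoods some packages default to because it is
deterministic to reason about and stricter — and clusters below the
extent k are dropped. The defaults k = 17/16/15 (tapping / imagery /
covariate) mirror common reporting; on synthetic grids k is fully
configurable since expected cluster size depends on the search volume.
ROI summaries are per-subject mean contrasts over a cluster, rank-
correlated with the improvement scores.

## Group statistics conventions

- One-sample t accepts raw samples or printed summary statistics
  (mean, SD, n) as first-class input; both give identical results.
- The repeated-measures ANOVA handles complete balanced subject ×
  A (× B) cell arrays. Mauchly's test runs per within factor with more
  than two levels (on subject-by-level means, collapsing the other
  factor); Greenhouse–Geisser ε scales an effect's degrees of freedom
  only when its factor's sphericity is rejected at α = 0.05, and the
  interaction is corrected when either of its factors failed. F, ε and
  corrected p come from pingouin; the conditional logic and the
  Mauchly-per-factor convention are this package's.
- Wilcoxon signed-rank drops zero differences and reports a *signed*
  tie- and continuity-corrected normal-approximation Z (positive when
  x tends to exceed y), with two-tailed p. At n = 6–7 the discrete
  null (granularity 1/32) limits agreement with exact enumeration to
  ~0.04 in the worst case; the tests assert mean deviation < 0.02 over
  random small-n datasets.
- Spearman uses mid-ranks and the two-tailed t approximation; constant
  input returns an undefined marker.

## Reproducibility

A single master seed derives named per-stage seeds through
`numpy.random.SeedSequence`, so sessions are bit-identical given (seed,
subject, config) and the full study report is byte-identical on re-run;
the report carries a config hash and the seed as provenance.
Intermediate artifacts (NIfTI volumes and masks, CSV schedules, tap
events, traces and score tables, JSON sidecars) are written to disk so
any stage can be re-run in isolation from its upstream outputs.

## Problem sizes used by the test suite

The suite exercises the decoder on ten single-subject sessions at the
default preset, the group covariate model on 20 null and 10 coupled
16-subject cohorts at the contrast-map level, the RM-ANOVA null on
1,000 replicates, and one complete 3-subject study run twice for the
determinism check; the acceptance script adds a complete 16-subject
study. These sizes keep the whole battery to a few minutes on one CPU
while leaving the Monte-Carlo intervals used by the calibration checks
meaningful.

## What the generator does and does not emulate

It emulates the statistical structure the analysis chain assumes:
block/event timing, hemodynamic convolution, drift, motion-coupled
nuisance, white noise, a distributed activation network, behaviorally
coupled per-subject effect sizes, and the practice-block kick-start.
It does not emulate anatomical geometry, physiological (cardiac or
respiratory) noise, slice-timing offsets, image realignment (motion
enters as known regressors, as the online analysis consumes it),
scanner reconstruction, or cerebellum-specific normalization. Passing
recovery tests here therefore validates the *computations*, not the
robustness of any step to real-data artifacts those steps never see.

## Known limitations

- The online nuisance estimator relies on the schedule-protection
  regressor; for paradigms whose task timing is unknown online, the
  plain history fit applies and its block-adaptation bias returns.
- The imagery contrast conditions on decoder output (true-ITAP events),
  so first-level effect sizes are entangled with decoder quality —
  faithful to the study design being simulated, but worth remembering
  when interpreting recovery rates.
- Whole-TR label shifting cannot represent sub-TR hemodynamic latency;
  boundary TRs carry irreducible ambiguity.
- The RM-ANOVA wrapper requires complete balanced data; missing cells
  are rejected rather than imputed.
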