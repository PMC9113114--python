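# Methods

## Scope and data model

The package implements the analysis chain of a case-control sensorimotor
study: precision-grip force variability, visually guided saccade precision,
cerebellar ROI volumetry, and their associations, with a synthetic-data
generator standing in for the human data so that every stage is testable
with known ground truth. Image processing (segmentation, registration,
manual correction) is upstream and out of scope; the volumetrics module
starts from a participant × ROI table.

## Grip scoring

Force traces (200 Hz, Newtons) are filtered with a 4th-order Butterworth
low-pass at 15 Hz applied forward–backward (`sosfiltfilt`), giving zero
phase so that rise-onset timing is not biased; the two-pass magnitude
response is the squared one-pass response, hence gain 1/2 exactly at the
cutoff. The end of the initial force rise is the earliest sample at which
(a) the rate of force increase — central-difference derivative of the
filtered trace — is below 5% of its peak, and (b) force lies within 90–110%
of the sustained-phase mean. Because (b) references a phase that is itself
delimited by the offset, the mean is resolved iteratively: it is initialized
from the final 12 s pre-cue window, the offset located, the mean recomputed
from the post-offset part of that window, and the rule re-applied once
(fixed point on all fixtures).

The sustained phase is the 12 s window preceding the stop cue intersected
with times after the rise offset, minus any zero-force span (force below the
transducer resolution of 0.0016 N) lasting *strictly more* than 1 s; a span
of exactly 1 s is retained. A trial is valid iff at least 8 s remain
(exactly 8 s passes). CoV = sample SD (n−1) / mean; with ~2,400 samples the
denominator convention is immaterial, and the natural log of CoV is the
modelling scale. MVC is the arithmetic mean of the three per-trial maxima
for each hand.

Under the generator's noise (below), rise-offset detection tracks the true
offset with median error < 30 ms; occasional low-frequency noise upswings
keep the measured rate above the 5%-of-peak threshold for longer, producing
a late-detection tail (roughly 1 trial in 12 beyond 50 ms at a latent CoV of
0.05). This is a property of the rule itself — no estimator of the
instantaneous rate removes in-band noise — and is harmless downstream
because the 12 s window bound, not the offset, delimits the sustained phase
in realistic trials.

## Saccade scoring

Gaze (500 Hz, degrees) is smoothed with a zero-phase linear-phase FIR
low-pass (31 taps, 50 Hz cutoff; the acquisition vendor's exact
transition-band design is not reproducible, so both parameters are exposed
in `SaccadeConfig`). Velocity is the central-difference derivative of
horizontal position. Saccades are maximal spans with |v| ≥ 30°/s lasting at
least 8 ms; each span's offset is the first sample back below 30°/s — the
onset threshold mirrors the stated offset threshold, a field-standard
symmetric choice. The primary saccade is the first event after target onset
whose amplitude covers at least 20% of the target distance (inclusive) in
the target's direction (direction congruence is a config toggle; a saccade
away from the target is not treated as a response). Latency ≤ 70 ms
(inclusive) excludes the trial as anticipatory. Error is the absolute
horizontal distance between eye position at the primary saccade's offset and
the target. Scoring is horizontal-only; the vertical channel contributes
only to artifact detection.

Blink handling replaces manual visual inspection with an automated
surrogate: missing samples or |v| above 1,000°/s, padded by 50 ms; a trial
is excluded if a span overlaps the 1,000 ms response window after target
onset. Condition summaries report the mean and sample SD of error per
amplitude (12/24°) × direction cell; cells with fewer than two valid trials
carry a null SD rather than an error.

## Volumetrics

Eighteen ROIs: left/right lobules I–V, lobule VI, Crus I, Crus II/lobule
VIIB (reported jointly), lobule VIII, lobule IX, lobule X; vermal I–V,
VI–VII, VIII–X; cerebellar white matter. The loader converts mm³ to cm³ on
request, validates the full schema (missing ROIs and unknown columns are
errors, never silently handled), and sums finer segmentation labels into the
composites via `data/roi_aliases.yaml`; label schemes differ across template
versions, so the map is a config file rather than a hard-coded assertion.
Raw volumes are analyzed without intracranial-volume normalization, and
`derive_composites` adds an exact 18-ROI total.

## Association models

All design factors are two-level, coded 0/1 (ASD, female, right, 24°,
rightward = 1); age is group-mean centered; ROI volume enters in cm³.
Models are random-intercept LMMs over participants: behavior group
contrasts (level 1: hand, or amplitude + direction), volume group contrasts
(level 1: hemisphere for the 7 lateral pairs; plain regressions for the 4
midline ROIs), brain–behavior models (level 2: group, volume, centered age;
sex as a covariate of no interest; three-way group × level-1 × volume sets
with their nested two-ways), and ASD-only clinical models (sex × volume
moderation; plain regressions for midline ROIs).

Variance components are estimated by REML (statsmodels `MixedLM`). On top
of the fit, the package computes closed-form GLS fixed effects and their
covariance C(θ) for the random-intercept structure, and per-term Wald F
statistics with **Satterthwaite** denominator df: df = 2(LCL′)²/Var(LCL′),
with the variance from the delta method using the finite-difference gradient
of LCL′ in θ = (σ²_b, σ²_e) and the inverse observed information of the
REML criterion. This reproduces lmerTest's fractional df (a test
cross-checks F, df and p against an independent lme4/lmerTest fit).

Interaction pruning operationalizes "removed if inclusion does not improve
fit": maximum-likelihood likelihood-ratio tests at α = 0.05, testing
removable terms of the highest remaining order first, removing one term per
pass (largest p first), never removing main effects and never removing a
two-way term while a containing three-way term remains; the final model is
refit by REML and the removal trace is recorded. Fits with a boundary
random-intercept estimate (σ²_b ≈ 0) fall back to OLS with residual df.

Benjamini–Hochberg control is applied per confirmatory family at q = 0.05
(step-up: reject all p(i) with i ≤ max{k : p(k) ≤ kq/m}); `p_crit` is the
largest passing threshold kq/m, reported as q/m when nothing passes. The
paper-style family structure — which p-values are pooled — is not uniquely
determined by the analysis description, so it is explicit in
`families.py`: the group contrasts across the 7 lateralized (and 4 midline)
volume models form one family each, and the volume terms of the primary
brain–behavior ROI set (lobules I–V, VI, Crus I per hemisphere for grip;
vermal VI–VII for saccades) form another; all other ROI models are flagged
exploratory and left uncorrected. Simple slopes evaluate the focal
predictor at each level of a two-level moderator as β_focal + m·β_int, with
SE from the coefficient covariance and Satterthwaite df for the contrast;
the level-difference equals the interaction coefficient identically.

## Synthetic data

**Calibration by moment-matched truncation.** Every calibrated scalar (age,
MVC, ADOS CSS, RBS-R, ROI volumes) lives on a bounded support, so each is
drawn from the truncated normal whose *truncated* mean and SD equal the
target values (parent parameters solved numerically). Naive truncation
would bias means — e.g. +2.4 points for a score with mean 29.5, SD 19
truncated at zero. Ages are drawn on [8, 30]; left/right MVC are coupled by
a Gaussian copula (ρ = 0.9) with matched marginals; sex and handedness use
deterministic rounded counts (a matched design, not a sample).

**Volumes.** Per-ROI group-specific means and SDs default to the published
cohort table values; effects enter additively (group, sex, group × sex,
hemisphere shifts; per-group age slopes applied to *centered* age so
marginal means stay calibrated — the default carries the reported TD
white-matter growth of 0.129 cm³/yr vs 0.035 in ASD). Draws are truncated
below at 0.1 × baseline for positivity.

**Force trials.** Baseline zero, reaction time ~0.35 s, then a half-cosine
rise (default 0.3 s — the task cues a maximally fast press, and ballistic
pinch-force rises take ~0.2–0.4 s) to a plateau at 15% MVC. Hold-phase
variability is multiplicative with an exact realized CoV equal to the
configured latent CoV; its spectrum is an equal-power pink/white mixture
band-limited to 0.4–12 Hz, so the 15 Hz scoring filter passes it nearly
untouched and CoV recovery is unbiased. Release events force zero-force
spans. Session-level latent CoV follows ln CoV = ln 0.045 + 0.35·[ASD]
− 0.03·age_c + N(0, 0.3²), giving ASD-elevated, age-declining variability.

**Saccade trials.** Fixation 1.5–2 s, target ±12°/±24° for 1.5 s; the eye
follows a clamped logistic whose duration obeys a main-sequence rule
(2.2 ms/deg + 21 ms), landing at gain × target; gain ~ N(0.95, 0.05) (mild
hypometria typical of visually guided saccades), latency ~ N(220, 40) ms.
Optional corrective saccades, blinks (missing samples) and white position
noise (0.02°) exercise the scoring stage's robustness. Sessions hold 60
trials in 2 blocks, 15 per amplitude × direction cell. Ground truth
(onset, offset, landing, latency, exact peak velocity of the clamped
profile) is annotated on every trial.

**Outcome-level simulators.** Parameter-recovery and type-I calibration of
the association stage need thousands of fits, so `simulate.outcomes`
generates scored outcomes directly from a linear mixed model with known
coefficients over the design codes (e.g. `{"group:volume": 1.0}` injects a
group-specific volume slope), a participant random intercept, and Gaussian
residuals — the exact generating process the models assume.

**What passing tests show.** Calibration tests establish that the
generators reproduce the published cohort's marginal moments and design
counts, and that the pipeline recovers injected effects under its own
assumptions. They do not establish anything about real force/gaze
recordings, whose artifacts (drift, head motion, partial blinks,
non-Gaussian tremor) are richer than the generator's failure modes; the
scoring rules themselves are therefore kept exactly as specified so they
transfer unchanged to real inputs.

## Numerical choices and problem sizes

Filtering uses second-order sections; boundary handling is scipy's default
odd-padding, exact for constant end segments. Boundary comparisons carry
±1e-9 relative guards so exact-boundary fixtures (1 s release, 8 s
retained, 70 ms latency, 20% amplitude) classify per the quoted inclusive /
exclusive semantics rather than by floating-point accident. Satterthwaite
derivatives use central differences with relative step 1e-4; singular
Hessians fall back to pseudo-inverse. The test suite runs the statistical
calibration at 200 null replicates (n = 100) for the type-I check, single
recovery runs at n = 400–500 per arm-pair for effect recovery, 10,000
fuzzed families for FDR equivalence, and 100–200-trial fixtures for the
scoring oracles; the acceptance script draws 10,000 participants per arm.
These sizes keep Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- The mixed-model engine supports the single random-intercept structure the
  analyses require; random slopes are out of scope.
- Multi-df terms (factors with > 2 levels) are supported by the design
  layer only via separate indicator terms; all study factors are two-level.
- The EyeLink ASC reader covers sample lines only (events are skipped);
  trial segmentation metadata must come from the manifest.
- Blink detection is an automated surrogate for manual inspection and will
  not catch artifacts that preserve plausible velocities.
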