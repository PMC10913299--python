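# Methods

This note documents the models, conventions and numerical choices behind
`startpheno`: a simulation and analysis pipeline for a tablet-administered
multi-task assessment of social, sensory and motor function in
2-to-7-year-old children from three groups — typically developing (TD),
autism spectrum (AS) and intellectual disability (ID).

## The assessment battery and its derived measures

Eight tasks produce raw per-child streams; the feature layer reduces each
to one or a few scalar measures under pre-set inclusion filters:

| task | raw stream | measure(s) | inclusion filter |
|---|---|---|---|
| preferential looking | frame-labelled gaze (20 Hz, 8 × 7.5 s trials) | social preference = social frames / (social + nonsocial frames) | eyes detected on ≥ 50% of frames AND gaze on tablet on ≥ 50% |
| button | 8 two-button choice trials | social choices / completed trials | ≥ 50% of scheduled trials completed (4/8 counts as included) |
| wheel | 5 × 15 s trials, face frames | looking time / (15 s × completed trials); min/max face-screen distance (mm) | ≥ 2 completed trials AND face detected on **more than** 25% of frames |
| motor following | target + finger trajectories (4 × 30 s trials) | RMSE, frequency gain (x, y), jerk | finger trace covers ≥ 50% of target time support; ≥ 2 valid trials |
| bubble popping | 21 aimed touches (trials of 1…6 bubbles) | mean pressure; mean \|Δx\|, \|Δy\| from bubble centre | ≥ 1 popped bubble |
| colouring | strokes on a 2 outlined figures | outline crossings (consecutive-sample inside/outside flips) | ≥ 25% of screen pixels painted |
| caregiver–child interaction | coder summaries | child-initiation and caregiver-synchrony proportions | video available (one coder chosen at random if several) |
| questionnaire | 14 binary items, 8 reverse-coded | total score 0–14 | always available |

Boundary conventions follow a literal reading of each filter clause: the
"at least 50%" filters are inclusive (≥), while the wheel face filter
excludes at exactly 25% ("25% or fewer"). Points exactly on the colouring
outline classify as *inside* (shapely `covers`), which makes the crossing
count deterministic for samples on the boundary. The wheel measure is
looking time (not played duration); the raw play duration is retained in
the records for the alternative definition.

Coordinates are screen pixels (origin top-left, y downward), timestamps
integer milliseconds, screen 2560 × 1600 px. Missing values are an
explicit `None` / empty CSV field, never a numeric sentinel.

### Frequency gain

The published battery reports a "weighted frequency gain" per axis without
a printed formula; the definition here is a reconstruction with the
properties the printed values imply (exactly 1 under perfect tracking;
greater than 1 when the child adds in-band motion; much larger on the
axis with little target motion). Both series are resampled to a uniform
50 ms grid over the overlapping support, linearly detrended, and their
one-sided DFT magnitude spectra compared over 0.2–5 Hz with weights
w(f) = f:

    gain_axis = Σ_f f·|C(f)| / Σ_f f·|T(f)|

where C is the child's and T the target's spectrum. The band and weights
are configuration fields.

### Jerk

Jerk is the mean magnitude of the discrete third difference of the
(uniformly resampled) finger trajectory divided by Δt³, normalised by
screen diagonal × a scale constant `jerk_scale_s3` (default 2 × 10³ s⁻³)
to a dimensionless index. No formula is printed for this measure either;
the normalisation is this package's own and the scale constant was chosen
once so that realistic trajectories produce values on the order of the
printed group means (~0.05). It is exposed in `ExtractionConfig`.

### Colouring coverage

Coverage is the fraction of pixels within the brush radius of any stroke
sample, computed by stamping rasterised discs on an integer pixel grid.
The denominator defaults to the whole screen, as the battery's inclusion
rule literally states; because that reading may be a misprint for
figure-interior pixels, `coverage_denominator="figure"` switches the
denominator to the figure interior.

## The synthetic cohort

The simulator emulates the field study's conditions: 40 TD / 48 AS / 43 ID
children, ages uniform on [2, 7.99), sex ratios 19:21 / 12:36 / 9:34
(female:male), eight raw task streams per child, and two sources of data
loss — *attrition* (a task entirely absent; per-group rates reproduce the
per-task "data available" counts) and *filter failure* (data present but
failing the pre-set filter, at the per-group rate implied by the
available-vs-final counts: e.g. low colouring coverage, fewer than half
the button trials completed, face detection below a quarter of wheel
frames, a single usable motor trial).

### Calibration

Group profiles carry a (mean, SD) target per feature, defaulting to the
published group summary table. The generators are parameterised so the
*extracted* features match these moments:

* **Direct-functional features** (choice probabilities, looking ratios,
  interaction proportions, crossing counts, face distances): a latent
  per-child parameter is drawn from a moment-matched distribution — Beta
  for [0,1]-bounded features, gamma for positive unbounded ones, normal
  for the face distances — and the raw stream realises it. Where the
  stream adds known sampling noise (binomial frame/trial counts, the mean
  of ~20 |offsets|, within-child pressure noise, occasional multi-coder
  selection noise) the latent variance is deflated by that exactly
  computed amount so the extracted SD still matches the target.
* **Questionnaire**: a beta-binomial — per-child latent endorsement
  probability, 14 items conditionally independent given the child. Fully
  independent items cannot reach the printed score SDs (e.g. TD 1.03 ±
  1.31 exceeds the maximal SD of 14 independent Bernoulli items with that
  mean), so the latent severity is what carries the overdispersion. The
  reverse-coded item set is the last eight indices (an arbitrary labelling
  with no effect on the score distribution).
* **Motor stream**: the finger trace is
  `target(t − lag) + offset + band noise + tremor` with a 100 ms reaction
  lag, a constant per-child offset, band-limited tracking noise
  (0.2–2 Hz) and a high-frequency tremor (5.5–9.5 Hz). Per-child targets
  for (RMSE, gain_x, gain_y) are drawn from moment-matched marginals
  (gamma for RMSE; 1 + gamma for the gains, which have a hard floor of 1)
  joined by a Gaussian copula (ρ = 0.6, reflecting that motor-impairment
  severity co-moves across measures while keeping the marginals exact);
  jerk is an independent gamma. The noise amplitudes are then *solved*
  per trial: noise is synthesised on exact DFT bins, so each band bin of
  the child's spectrum is Rician with known parameters and the expected
  weighted magnitude sum is available in closed form (modified Bessel
  functions); 1-D root finding gives the band amplitude matching the gain
  target, and likewise the tremor amplitude for the jerk target. The
  constant offset absorbs whatever RMSE budget remains — a constant is
  annihilated by detrending, so it moves RMSE without touching the
  spectral gains. In the rare physically inconsistent corner (a tiny RMSE
  draw with a large jerk draw) the jerk target wins and RMSE overshoots.
* **Butterfly target**: speed follows a slow sinusoid spanning the
  configured velocity range (default 60–140 px/s) and the heading
  oscillates about horizontal with amplitude proportional to the relative
  velocity spread; the path reflects at screen margins and the sweep
  direction alternates across trials. A degenerate velocity range yields
  a straight horizontal path.

Per-child and per-task random streams are split deterministically from
the master seed (`numpy` `SeedSequence` spawning), so adding a task to
the battery does not perturb the other streams, and identical
(config, profiles, seed) reproduce an identical cohort bit for bit.

### What the simulator does and does not emulate

The simulator reproduces feature-level group distributions, per-task
participant counts, and raw streams that are *consistent* with those
features under this package's extraction definitions. It does not model
real gaze or touch dynamics (no saccade structure, no fatigue or learning
across trials, no spatial structure in where children colour), inter-task
correlations beyond the motor copula, or age/sex effects (both are
simulated but, as in the source analysis, not used as covariates).
Passing tests therefore demonstrate the internal consistency of
extraction + statistics + classification under realistic group-level
signal, not the behaviour of real children.

## Statistics

* One-way fixed-effects ANOVA in raw and summary-statistic form. The
  summary form uses the definitional sums of squares
  (SS_b = Σ nᵢ(mᵢ − m̄)², SS_w = Σ (nᵢ−1)sdᵢ²), which lets printed
  n/mean/SD rows reproduce printed F values; the two forms agree to
  10⁻⁹ relative on identical data (a tested invariant).
* Partial eta-squared η²p = F·df₁/(F·df₁ + df₂).
* Post hoc pairwise t tests use the pooled within-group mean square with
  Bonferroni multiply-and-cap adjustment (the only rule producing printed
  adjusted values of exactly 1.00).
* Robust alternatives: Welch and Brown–Forsythe mean tests (implemented
  directly; Welch is cross-checked against `pingouin` in the test suite)
  and Kruskal–Wallis / Levene / Shapiro–Wilk via `scipy`. A dispatcher
  runs the robust variant when the corresponding assumption check fails
  at α = 0.05 and reports both results, never silently substituting.
  Which measures triggered the robust variants in the original analysis
  is not recorded; α = 0.05 with Shapiro–Wilk is this package's default.
* Pearson chi-square of independence without continuity correction.
* ICC(A,1) — two-way mixed-effects model, absolute agreement, single
  measure — from the mean squares, with the standard F-based p value and
  95% confidence interval for absolute-agreement coefficients
  (cross-checked against `pingouin`'s ICC(A,1) row).

Degenerate inputs (all groups constant and equal, zero ratings variance)
raise an explicit error rather than returning NaN.

## Classification

Each task contributes a feature block (So1 button, So2 preferential
looking, Se1 wheel, Mo1 motor following, Mo5/Mo7 bubble offsets/force,
Mo-col colouring, Ob1 interaction, Ob2 questionnaire). Blocks are
evaluated alone or in combination with stratified 5-fold cross-validation
repeated 20 times; median imputation is fitted inside the pipeline on
training folds only (tested with a spy on the imputer). Per-class
accuracy is class recall; "predicted proportions" are the mean
predicted-class shares; a TD-vs-NDD binary accuracy is recomputed from
the retained per-sample predictions by collapsing AS and ID. The default
classifier is gradient boosting, with logistic regression and an SVM
available. Exhaustive subset search ranks all non-empty block subsets by
mean overall accuracy, breaking ties toward fewer blocks then
lexicographic ids. The published headline accuracies depend on the
original raw data and are deliberately not targets; the package's
acceptance surface for this layer is the chance-level baseline
(permuted labels ≈ 33.3%) and structural properties.

## Problem sizes and tolerances

The test suite runs the simulator at 500 children per group for moment
calibration (each extracted feature's mean within 3 standard errors of
its target, and its SD within 3 standard errors computed from the target
marginal's kurtosis — proportions and heavy-tailed gamma marginals make
the normal-theory SE of an SD too tight) and 100 replicate 131-child
cohorts for the group-difference direction check (the printed TD-vs-AS
sign reproduced in ≥ 95% of replicates for every measure with a printed
significant contrast). Root finding uses Brent's method with 10⁻⁹
tolerances; spectra are computed on exact DFT grids so no windowing is
needed; serialisation uses shortest-round-trip float rendering so
write→read→write is byte-identical.

## Known limitations

* Frequency-gain and jerk definitions are reconstructions (no printed
  formulas); their absolute scales are convention-dependent, although
  the group ordering and calibration are scale-free.
* The motor copula correlation (0.6) and the coder-noise SDs of the
  interaction simulator are plausible choices, not estimates from data.
* The motor feature table reports identical per-task ns for RMSE and the
  FFT gains (both derive from the same valid trials), whereas the source
  tables print slightly different ns for these rows; the availability
  targets follow the task-level counts.
* The colouring figure is a stylised chamfered rectangle, not the
  flower/butterfly line art of the real task; crossing counts and
  coverage are figure-shape-agnostic.
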