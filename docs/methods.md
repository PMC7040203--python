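# Methods

## Movement segmentation

The hand is tracked by the *grip center*, the per-sample mean of the
thumb, index and middle fingertip positions. Using the centroid rather
than a single finger makes the choice explicit and symmetric in the
fingers; the aperture (thumb and index moving apart symmetrically) cancels
in the mean, so grasp shaping does not leak into transport kinematics.
Velocity is estimated by central differences (one-sided at the series
edges); speed is the Euclidean norm of the 3-D velocity. No smoothing is
applied by default — an optional zero-phase 4th-order Butterworth low-pass
(`smoothing_hz`, typically 10 Hz) is available for noisy recordings but is
off in every validation.

A movement onset is the **first sample** of the first run of at least
`min_run = 10` consecutive samples with speed above
`velocity_threshold = 30 mm/s`; the offset is the first sample of the next
run of at least 10 samples below it. Timestamping the onset at the run's
first sample keeps `onset + duration` arithmetic exact, and
`adjustment_time + (peak_time − onset_time) = duration` holds identically.
Ties in peak speed resolve to the earliest sample. Segments whose peak
falls on a boundary sample are retained but flagged degenerate; an
adjustment time of 0 is legal. A movement still above threshold when the
recording ends is dropped with a warning.

Labels are geometric: a segment whose terminal grip-center position lies
within 60 mm *horizontally* of pick-up location A is the reach; a segment
from near A to near put-down location B is the transport. Horizontal
distance is used because the grip center travels at grasp height above
table-level landmarks. Manual per-segment label overrides are accepted and
win over geometry, mirroring analyst-coded segment identities.

## Grasp geometry

The object is modeled as a solid conical frustum even though a cup is a
shell: the analysis convention is the geometric frustum centroid, and the
printed outer radii (28.5 and 43.5 mm) stand in for the unspecified wall
profile. From the base,

    COM = h (R1² + 2 R1 R2 + 3 R2²) / (4 (R1² + R1 R2 + R2²)).

For the filled cup, cup (11 g) and liquid (241 g) centroids combine by the
mass-weighted mean. The liquid's fill height is an explicit input rather
than being derived from its mass: treating the liquid as water filling the
frustum from the base would put the combined COM near 39 mm, which is
inconsistent with the reported 46 mm, so the fill height cannot be
reconstructed from the reported masses alone. The default, 82 mm, is the
value at which the combined COM reproduces 46 mm; anyone with the true
fill height can supply it.

The MGA uses thumb–index distance only; the middle finger enters only the
grip center. The contact instant is the reach offset sample (speed
re-crossing the threshold) — the only definition consistent with the
segmentation rule. Grip placement requires all three fingertips tracked at
that exact sample; no imputation is permitted at the measurement instant.
The grip center is the mean of the three fingertip *z* coordinates (the
literal reading of a vertical grip-center position). Relative MGA timing
is allowed to be exactly 0 when the aperture is monotonically closing from
the onset sample (the tie rule puts the maximum there).

## Missing data

Dropout runs of at most 5 samples (50 ms at 100 Hz) are linearly
interpolated per axis when flanked by valid samples; longer runs, and runs
touching the recording boundary, stay invalid. Any surviving gap inside a
detected movement span excludes the trial from analysis — mirroring how
dropout-heavy recordings are excluded in practice rather than guessed at —
and every exclusion is recorded with its reason in a dispositions table.

## Synthetic trials

The generator emulates the study design: `n_participants = 14` × 5 blocks
× the 2×2×2 surface/content/feedback factorial, one trial per cell per
block (560 trials), 100 Hz, 400 mm reach (start → A) and 400 mm transport
(A → B).

**Kinematic family.** A reach is two half-minimum-jerk pieces joined at
the velocity peak, with speed continuous at the junction and zero at both
ends. This family fixes peak speed at `1.875·D/T` for any split of the
total time T, so the deceleration fraction — hence the adjustment time —
is directly injectable. A consequence worth knowing: with D = 400 mm and
measured durations of 1.4–1.65 s, the family's reach peak is ~470–540
mm/s, so reach-duration targets and a ~1000 mm/s reach peak cannot be
injected simultaneously; the generator treats duration and adjustment time
as the targets and lets the reach peak follow. The transport is a single
symmetric minimum-jerk whose duration is chosen to hit the configured
transport peak.

**Threshold calibration.** Measured movement boundaries clip the profile's
sub-threshold tails, which would shorten every measured span by ~60–120 ms
relative to the internal profile time. The generator solves (closed form
for the crossing point `u* = (1 − √(1 − 4g))/2`, `g = √(thr/(16 v_p))`,
plus a short fixed point in T) for internal durations such that the
*measured* duration and adjustment time of the noise-free profile equal
the configured targets. Configured means are therefore on the same scale
as the analysis output.

**Default targets** are the reported condition means of the reference experiment: measured
reach duration 1400 (empty) / 1640 ms (filled); adjustment time 881 / 1024
ms; transport peak 834.01 / 657.46 mm/s; MGA 119.61 mm with relative
timing 66.78 % / 61.67 %; grip deviation +8 mm (empty; reported only as an
upward deviation, so the magnitude is a package choice) and −16.57 mm
(filled). Random intercepts per subject (SDs 90 / 70 / 60 ms·mm/s, 3 %,
8 mm, 4 mm for duration / adjustment / transport peak / MGA timing / MGA /
deviation) and trial-level noise (150 / 110 / 90, 5 %, 10 mm, 6 mm) are
chosen so that the marginal SDs land near the reported ones; the
within-subject correlation structure is not reported, so the split between
the two levels is a package choice.

**Aperture.** The aperture rises from a 40 mm rest opening to the trial's
MGA at the configured fraction of the measured reach and closes to the cup
diameter at the grasp height, using raised-cosine pieces. The raised
cosine has a quadratic (non-degenerate) maximum; a flatter profile (e.g.
minimum-jerk pieces, cubically flat at the peak) lets marker noise carry
the argmax along the plateau and visibly biases the recovered MGA-timing
effect.

**Noise and dropouts.** Gaussian marker noise (0.15 mm per axis,
consistent with sub-0.4 mm optical-tracking residuals) and contiguous
dropout runs (start probability 0.002 per sample, geometric lengths, mean
3) are applied last. With these defaults ~8 % of trials lose a movement
window to an unfillable gap and are excluded — the generator deliberately
exercises the exclusion path. All randomness flows from one seed through
per-trial counter-derived substreams, so any subset of a dataset
regenerates identically.

**Ground truth** per trial stores the threshold-rule boundaries of the
noise-free sampled profile and the feature values measured on it, so a
noise-free trial analysed by the pipeline reproduces its ground truth to
one frame / 1e-6 mm. A feature-level fast path
(`simulate_feature_table`) samples the same generative feature
distribution without trajectory synthesis; it exists for calibration
studies that need thousands of replicate datasets and adds only the
trajectory layer's sub-frame discretisation error.

**What the generator does not emulate:** hand-path curvature and lift
height (the grip height is constant per trial), finger-specific kinematics
beyond the aperture, velocity-profile asymmetries other than the two-piece
family, block-order learning effects, and any dependence of marker noise
on speed. Passing recovery tests therefore show that the pipeline measures
what this family encodes — not that real recordings satisfy the family.

**Ratings** come from the matching cumulative-link generative model:
latent value = effect·covariates + subject intercept (SD 1) + standard
logistic noise, binned by six symmetric thresholds (±0.5, ±1.5, ±2.5).
Default effects are the coefficients reported for the reference experiment
(content 1.98 / 1.41 on heaviness / hardness; surface 6.89 on glossiness).

## Statistics

*rm_anova* computes the balanced fully-within decomposition natively on
subject-by-cell means (each effect tested against its subject
interaction; no sphericity correction, conventional for 2-level factors)
because generalized eta squared is not available from `statsmodels`
AnovaRM; F and p are cross-checked against AnovaRM and η²G against
pingouin in the tests. η²G counts every subject-involving SS in its
denominator, treating all design factors as manipulated.

*lmm_fit* wraps `statsmodels` MixedLM (ML, not REML, so that
likelihood-ratio tests of nested fits are valid); each term's χ²(1) comes
from an ML refit without it, matching the conventional reporting style.
Wald z p-values are available (`lrt=False`) for bulk simulations. A
boundary (≈0) random-intercept variance warns and degrades gracefully to
OLS estimates.

*clmm_fit* is a native proportional-odds logit model with a participant
random intercept; mixed ordinal models have no canonical scientific-Python
implementation. The marginal likelihood uses adaptive Gauss–Hermite
quadrature (default 21 nodes): per subject, eight Newton steps locate the
integrand's mode and curvature with analytic first and second derivatives,
and the nodes are recentred and rescaled there. Thresholds stay strictly
increasing via a log-difference parameterization; the random-intercept SD
is optimised on the log scale within [e⁻⁷, e³], and `fix_sigma` holds it
fixed (0 gives the fixed-effects cumulative-link limit, used by the
validation suite). Starting values come from a pooled `OrderedModel` fit;
standard errors from the numerical Hessian. Validation is two-sided: the
σ→0 limit against `statsmodels` OrderedModel, and the σ>0 path against
`lme4::glmer` on the binary collapse with matched quadrature (agreement
~1e-5 observed).

*kruskal_wallis* wraps `scipy.stats.kruskal` (tie-corrected) with an
explicit degenerate flag when every value ties.

No multiple-testing correction is applied, matching common practice for
this design; block-wise analyses are separate per-block fits rather than a
block-interaction model.

## Validation problem sizes

The heavy validations are sized to finish comfortably on one CPU:
parameter recovery runs 200 replicate datasets at full study scale (14 ×
5 × 8 trials each, ~3.5 min); CLMM sign recovery 200 replicates of 14
participants × 8 stimuli (11 quadrature nodes, ~1 min); type-I-error
calibration 1000 replicates of a reduced 12-participant × 2-block null
design via the feature-level fast path (~1.5 min); segmentation
equivalence 1000 random piecewise-constant speed series; the frustum
quadrature oracle 200 random frusta at 1e-8 relative tolerance.

## Known limitations

* Measured peak velocities carry a small positive bias under marker noise
  (the maximum of a noisy series exceeds the noise-free maximum; ~+30 mm/s
  at the default noise). Condition contrasts are unaffected, which is what
  the recovery validations test.
* The C3D codec covers the common Intel/floating-point point-data layout
  only (no analog channels, no integer scaling).
* `rm_anova` requires a complete subject × cell design after aggregation.
* The CLMM supports a single random intercept (by participant); crossed
  random effects (e.g. by stimulus) are out of scope.
* Landmark-based labeling assumes reaches terminate near location A; other
  paradigms should supply manual labels.
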