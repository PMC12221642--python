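# Methods

`pigeongaze` reconstructs where motion-captured pigeons look and tests how
gaze following scales with the number of demonstrating birds. This note
documents the models, the assumptions, the tunable parameters, what the
synthetic-data generator does and does not emulate, and the numerical
choices made where the design was open.

## Head pose from rigid marker sets

Each bird carries four head markers whose positions relative to the eyes
and beak tip are known from a per-bird calibration (the calibration itself
is an input: it is produced upstream by a multi-camera reconstruction and
supplied as a CSV of template-frame points). Each frame, the observed
markers are aligned to the calibration template by the least-squares rigid
transform (Kabsch via SVD, determinant-corrected so a reflection is never
returned). Frames with fewer than three valid markers are unusable and
stay invalid rather than raising.

The head-local coordinate system follows the anatomical convention: origin
at the eye midpoint; the forward (+Y) axis is the origin-to-beak-tip
direction rotated 30 degrees upward in elevation (pigeons hold the beak
about 30 degrees below their visual horizon), within the plane spanned by
the beak direction and a head-up reference; +X points toward the right
eye; Z = X x Y. In this frame the beak direction has exactly -30 degrees
elevation and 0 azimuth by construction. The anatomical definition fixes
only the origin and the Y axis; the X/Z handedness convention is ours, and
it makes signed azimuth well defined (negative azimuth = left fovea).

The roll of the frame about the beak direction is resolved by a head-up
reference recorded in the calibration (the unit vector normal to the eye
axis closest to world-up in the calibration posture; default world-up).
This keeps the frame rig-independent: a recalibration in a tilted posture
reproduces the same head frame.

### Smoothing and masks

Marker dropouts up to `max_gap_frames` (default 10) are bridged by linear
position interpolation and spherical rotation interpolation; longer gaps
stay invalid. A zero-phase Butterworth low-pass (order 2, default cutoff
10 Hz) is applied per contiguous valid run to positions and to
orientations (via sign-continuous quaternion components, renormalized, so
rotations remain orthonormal).

Head saccades — rapid reorientations during which avian visual processing
is suppressed — are flagged frame-wise: a frame is a saccade frame when
the geodesic angular speed from the previous valid pose exceeds
`saccade_threshold_deg_s` (default 300 deg/s; the threshold is a
configurable stand-in, since the upstream detector of the original
pipeline lives in companion software). Angular speed is estimated on a
running-median pre-filtered orientation track (window 5 frames) rather
than the low-passed one: a median suppresses frame-to-frame jitter without
smearing a genuine step across neighbors, so the flagged interval stays
tight around the true jump; a linear low-pass would spread one saccade
over three or more flagged frames and systematically delay bout onsets.

Grooming is detected by a reference heuristic — head pitched below
`grooming_pitch_threshold_deg` (default -45 degrees) with the eye midpoint
within `grooming_backpack_dist_m` (default 0.15 m) of the bird's backpack
centroid, sustained for `grooming_min_ms` (default 300 ms) — or an
externally supplied per-frame mask is passed through verbatim. The dual
path exists because the original detector is external; the heuristic
captures its operational signature (head buried toward the back).

## Gaze cones and looks

Head orientation proxies gaze. Three visual-field cones are modeled, all
with apex at the eye midpoint: the two lateral foveas at +/-75 degrees
azimuth, 0 elevation, and the frontal binocular field at 0/0, each with a
10-degree half-angle by default (the 10-degree margin accommodates eye
movement and noise; for the binocular cone it matches the ~20-degree
binocular overlap of pigeons). The lower-frontal field is deliberately not
modeled. Using one apex for all cones errs by under 0.6 degrees at the
rig's meter-scale distances.

A region of interest is a 0.25 m-radius sphere (50 cm diameter) around a
stimulus-window center. A cone hits a sphere when the apex is inside it or
the angle between the cone axis and the apex-to-center direction is at
most the half-angle plus the half-angle subtended by the sphere,
arcsin(radius/distance).

Frame-wise "looking" at an ROI is the OR over the three cones, AND pose
valid, AND NOT saccade, AND NOT grooming. Maximal runs of at least
`fixation_min_ms` (300 ms) become look bouts; shorter runs are discarded
as gaze passings. Saccade/grooming frames break runs outright (no gap
bridging): the exclusion is a frame-level statement. Simultaneous hits by
several cones are one look, labeled with the cone holding the majority of
hit frames (ties go to a fovea); this avoids double-counting a single
orienting event, and whether the original pipeline counted overlapping
cone hits separately is unstated — the OR-then-segment rule is our
documented choice. Bouts are clipped to presentation windows.

## Presentation tables and exclusions

Each presentation splits birds into demonstrators (on the table side
facing the open stimulus window) and observers. Sides are assigned from
the median backpack position within the window; a bird whose tracked
position leaves both table boxes is flagged flown-off, one whose box
membership changes is flagged switched, and a wholly untracked bird is
flagged untracked (an untracked bird has no side and hence contributes no
analysis row).

One analysis row is one observer in one presentation: whether/how often it
looked at the target (the presenting location) and the distractor (the
other location), which it looked at first (identical onset frames give
"none" — unbiased and rare), the number of demonstrators, and the "actual
number of demonstrators": demonstrator-side birds with at least one target
bout that overlaps at least one frame in which the observer is not
grooming. The any-overlap rule (rather than requiring the whole bout
outside observer grooming) is our documented choice; it is monotone —
removing observer grooming never decreases the count. A
mean-demonstrators-looking covariate (time-average number of
demonstrators with an ongoing target bout) is emitted as an optional extra
column and unused by the default models.

Exclusions: rows of flown-off/switched observers, and all rows of test
presentations in which no demonstrator looked at the target. The latter is
evaluated on demonstrator bouts before observer-grooming filtering — it is
a property of the presentation, not of an observer — and does not apply to
control presentations.

## Mixed models

Responses are binary (looked at the target: binomial, logit link) or
counts (number of looks: Poisson, log link). Main predictors: condition
(coded control = 0, test = 1, so positive coefficients mean stronger
responses under demonstration) or the (actual) number of demonstrators.
Control predictors: trial number, presentation number, presentation
location, and experiment id in combined analyses. All numeric predictors
are z-scored (ddof = 1) on the modeled rows, per dataset, with the scaling
recorded for back-transformation. Random structure: per-individual
intercept plus random slopes for all fixed effects, with estimated
correlations.

The engine is a Laplace-approximate maximum-likelihood GLMM fitted by
penalized IRLS over (fixed effects, spherical random effects) inside a
profiled optimization over the random-effect Cholesky factor (diagonal
entries bounded at zero, so variances can vanish at the boundary). The
penalized system is block-diagonal per individual, solved by a Schur
complement, so each iteration is linear in the number of rows. Fixed-
effect covariance is the fixed-effect block of the inverse penalized
information matrix at the optimum. Against lme4 on identical data the
slopes agree to ~1e-3, the log-likelihood to ~0.05 (both Laplace variants
bracket the adaptive-quadrature value), and likelihood-ratio statistics to
~1e-2; lme4 serves as an independent cross-check in the test suite, never
as the implementation. Laplace fits of Poisson models with random slopes
carry a known mild attenuation of fixed effects (a few hundredths on the
z-scored scale), visible in the recovery harness and shared with lme4.

Non-convergence triggers a documented fallback ladder — correlated ->
uncorrelated (diagonal) -> intercept-only — with the rung recorded in the
result, so any deviation from the full random structure is explicit.
Degenerate fits (separation, coefficients beyond +/-15 on the z-scored
scale, non-finite likelihood) are flagged, never raised.

Each main predictor's chi-square(1) is a likelihood-ratio test against the
model without that fixed effect, refitted with the identical random
structure; a Wald option exists. Model comparison uses AIC with the number
of free covariance parameters counted. Confidence bands for predictions
simulate 10,000 fixed-effect vectors from their asymptotic normal
distribution and take 2.5th/97.5th percentiles of response-scale
predictions with other design columns at their means. Diagnostics:
Pearson-chi-square/df overdispersion (Poisson), variance-inflation factors,
and leave-one-individual-out Cook's distances. No multiple-testing
correction is applied — each question is pre-specified and tested once.

## The synthetic-data generator

Two generators make every stage testable with known ground truth.

**Flock scenarios** emulate the group set-up: ten birds standing on two
parallel tables flanking a tube structure with top and bottom stimulus
windows (ROI centers at x = 0), shuffled between presentations, at 60 Hz
(the capture rate is not a published quantity; it is required
configuration, and 60 Hz is the generator's default). Head orientation
follows avian head-saccade dynamics: piecewise-constant fixations
(350–900 ms) separated by instantaneous jumps of at least 25 degrees.
Scheduled look events aim a designated cone's center line exactly at an
ROI center, with the free roll about that line chosen to keep head-up
near world-up while keeping every other cone/ROI pair outside its
acceptance angle (otherwise a correctly working pipeline would report an
unscheduled second look). Wandering fixations keep all cones at least 30
degrees from every ROI direction and re-sample whenever the bird's
standing position jumps. Grooming bouts pitch the head to -60 degrees next
to the backpack. Marker noise is isotropic Gaussian (default 0.5 mm per
coordinate, typical of marker-based capture) and markers drop out
independently (default 1%). Scripted table switches and fly-offs leave
after the window midpoint so the bird's median position (hence its
reported side) stays the start side.

By construction, supra-threshold scheduled events are recovered one-to-one
with onset error at most 2 frames: the saccade into an event claims the
first frame, and the low-pass smear can claim one more. This guarantee
holds for scenarios without scripted departures; scripted birds exist to
test the exclusion bookkeeping, not bout recovery.

What the generator does **not** emulate: locomotion and head-bobbing,
feeding, occlusion between birds, marker identity swaps (the upstream
relabeling problem is out of scope — gaps and dropout stand in for it),
eye-in-head movement, and correlated or non-Gaussian marker noise. Passing
recovery tests therefore demonstrates the pipeline's correctness on its
own model of the data, not robustness to every artifact of a real rig.

**Response tables** are the statistical twin of the analysis tables:
binary looks ~ Bernoulli(logit^-1(eta)) and counts ~ Poisson(exp(eta))
with eta = intercept + beta_cond * condition + beta_dem * z(count)
[+ beta_dem2 * z(count)^2] + per-individual random intercept and slopes.
Defaults are the study conditions the analysis targets: beta_cond = 0.425 (the
condition effect on the number of looks), beta_dem = 0.324 (the combined
demonstrator-count effect), baseline -0.3 on the log scale (about 0.7
looks per presentation at control), random intercept sd 0.5 and slope sd
0.2 (moderate individual heterogeneity), 70 individuals x 21 presentations
(~1,500 rows, the combined-analysis scale). Demonstrator counts are
Binomial(9, 0.5) — an observer faces between 0 and 9 demonstrators in a
ten-bird flock. Scheduled look events use a fovea 92% of the time (evenly
left/right) and the binocular field 8%, the usage split observed in real
pigeon flocks on this kind of stage.

## Harness problem sizes

The replicate studies use: CI coverage — 200 replicates at the combined
scale with diagonal random slopes on the count and condition terms (the
terms the generator actually varies; slopes on pure-noise controls slow
the fits without changing coverage); test size — 1,000 replicates at 40
individuals x 8 presentations with intercept-only structure; AIC selection
— 200 replicates, intercept-only. The AIC study generates with the count
random slope off: marginalizing a lognormal random slope induces a real
quadratic term (sigma^2 z^2 / 2), so "linear truth" requires it absent.

## Known limitations

- The saccade and grooming detectors are principled stand-ins for the
  companion pipeline's detectors; their thresholds are configuration, not
  published values.
- Exact reproduction of coefficients estimated from a real recorded
  dataset requires that dataset; the statistical twin verifies
  recovery of effects of the published size at the published scale, which
  is a calibration statement, not a reproduction of the original birds.
- Laplace (rather than adaptive-quadrature) likelihoods share lme4's
  default accuracy; with few observations per individual both can be a few
  hundredths off in the fixed effects.
- The pipeline assumes bird identities are already correct in the marker
  file; identity repair belongs upstream.
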