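# pigeongaze

Gaze-following analysis for motion-captured pigeon flocks: from raw 3D
head-marker trajectories to head poses, visual-field gaze cones,
region-of-interest "looks", per-presentation observer response tables, and
generalized linear mixed models of how gaze following scales with the
number of demonstrating birds.

## The problem

Gaze following — reorienting one's own gaze to where another individual is
looking — is usually studied in dyads. In a flock on a motion-capture
stage, a varying number of *demonstrators* can see a moving object through
a one-sided window while *observers* on the opposite table cannot; the
question is whether observers look more at the object's location when
demonstrators cue it (test vs control), and whether the response grows
with the number of demonstrators actually providing a cue — linearly or
with a quorum-like quadratic bend.

Pigeons have no fine eye tracking on a stage, but their head *is* their
gaze: two lateral foveas project at ±75° azimuth and the binocular field
straight ahead. The pipeline reconstructs each bird's head-local frame
from four head markers plus a per-bird eye/beak calibration (origin at the
eye midpoint, forward axis 30° above the origin–beak line), projects the
three visual-field cones (10° half-angle) into the world, and calls
"looking" any ≥300 ms run of a cone crossing a 0.25 m ROI sphere around a
stimulus window, after excluding head-saccade and grooming frames.

Each observer × presentation becomes one row: `looked_target` (0/1),
`n_looks_target`, `first_look`, and the *actual number of demonstrators*
(demonstrator-side birds with ≥1 target look the observer could have
seen). These feed mixed models

```
looked  ~ predictor + controls + (1 + predictor + controls | individual)   [binomial]
n_looks ~ predictor + controls + (1 + predictor + controls | individual)   [Poisson]
```

with z-scored numeric predictors, likelihood-ratio χ²(1) per main
predictor, AIC comparison of linear vs quadratic demonstrator-count
effects, simulation-based confidence bands (10,000 draws), and
overdispersion / VIF / Cook's-distance diagnostics. The GLMM engine is an
in-package Laplace-approximation maximum-likelihood fitter (lme4-style
PIRLS with a profiled covariance factor), cross-checked against lme4 in
the test suite.

A first-class synthetic-data module generates both marker-level flock
scenarios (rigid 4-marker heads, scheduled gaze events, saccade jumps,
grooming, noise, dropout) and presentation-level response tables with
known effect sizes, so every stage is testable against ground truth
without any recorded data.

## Worked example

Simulate a 10-bird session, run the pipeline, and look at what it found:

```python
from pigeongaze import (default_scene_config, default_calibration,
                        random_scenario, generate_flock_trajectories,
                        run_pipeline)

cfg = default_scene_config()            # 60 Hz, two tables, top/bottom ROIs
calib = default_calibration()
sc = random_scenario(cfg, n_birds=10, seed=1)
markers, truth = generate_flock_trajectories(sc, calib, cfg)
res = run_pipeline(markers, {b: calib for b in markers.bird_ids},
                   sc.schedule, cfg)
print(len(truth.events), len(res.bouts), res.field_usage)
```

```
scheduled look events: 53
recovered bouts:       53
field usage:           {'foveal': 0.981, 'binocular': 0.019}
analysis rows kept:    44
```

Every scheduled look came back as exactly one bout (onsets within two
frames), and the foveal/binocular split of the bouts reflects how the
events were scheduled. Fitting the demonstrator-count model on a
statistical-twin table at the combined-data scale:

```python
import numpy as np
from pigeongaze import EffectSpec, GlmmSpec, generate_response_table, fit_glmm, simulate_ci

table, truth = generate_response_table(EffectSpec(), seed=7)   # beta_dem = 0.324
spec = GlmmSpec(family="poisson", response="n_looks_target",
                main_predictor="n_actual_demonstrators",
                control_predictors=["condition", "trial_id",
                                    "presentation_index", "presentation_location"],
                structure="diagonal",
                random_slope_terms=["n_actual_demonstrators", "condition"])
res = fit_glmm(spec, table)
print(res.report())
```

```
poisson GLMM: n_looks_target ~ n_actual_demonstrators + condition + trial_id + presentation_index + presentation_location
random structure: diagonal (fallback path: diagonal)
n_obs = 1470, n_individuals = 70, AIC = 4059.7, converged = True
  intercept                    beta = -0.177  se = 0.078
  n_actual_demonstrators       beta = +0.253  se = 0.037
  condition                    beta = +0.378  se = 0.060
  ...
  test n_actual_demonstrators  chi2(1) = 35.637, p = 0.0000
```

The generating coefficient (0.324 on the z-scored scale) sits inside the
fitted 95% CI (0.253 ± 1.96·0.037). `simulate_ci(res,
"n_actual_demonstrators", np.array([-1, 0, 1]))` returns the
response-scale prediction band: about 0.79 looks per presentation one
standard deviation below the mean demonstrator count, rising to 1.31 one
standard deviation above.

## Command line

```bash
pigeongaze simulate --seed 1 --out data/       # markers, schedule, calibration, ground truth
pigeongaze pose   --markers data/markers.csv --calibration data/calibration.csv \
                  --config data/scene.yaml --out poses/
pigeongaze looks  --data data/ --out bouts.csv
pigeongaze table  --data data/ --out table.csv
pigeongaze fit    --table table.csv --predictor n_actual_demonstrators --out report.csv
pigeongaze run-all --seed 1 --out run/         # the whole chain
```

All thresholds (cone angles, ROI radius, 300 ms fixation minimum, saccade
threshold, smoothing) live in the scene YAML — nothing is hard-coded.

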