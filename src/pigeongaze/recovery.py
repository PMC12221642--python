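"""Parameter-recovery, calibration and model-selection harnesses.

These simulation studies run the statistical twin (`generate_response_table`)
through the mixed-model stage many times to verify, under known ground
truth, that (a) the 95% confidence interval for the demonstrator-count
effect covers the generating value at the nominal rate, (b) the
likelihood-ratio test holds its size under the null, and (c) AIC prefers
the linear model when the truth is linear. Replicate fits use a reduced
random structure (diagonal, slopes only on the terms that actually vary by
individual in the generator — or intercept-only for the null studies) to
keep many replicates affordable.
"""

from __future__ import annotations

import numpy as np

from .stats import GlmmSpec, compare_models, fit_glmm
from .synthetic import EffectSpec, generate_response_table

DEM = "n_actual_demonstrators"
CONTROLS = ["condition", "trial_id", "presentation_index", "presentation_location"]


def _rep_seeds(seed: int, n_reps: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n_reps) % (2**31 - 1)


def ci_coverage_study(
    n_reps: int = 200,
    seed: int = 0,
    effect: EffectSpec | None = None,
    level: float = 0.95,
) -> dict:
    """Fraction of replicates whose Wald CI for the demonstrator-count
    coefficient covers the generating value (Poisson number-of-looks model
    at the combined-data scale)."""
    effect = EffectSpec() if effect is None else effect
    spec = GlmmSpec(
        family="poisson",
        response="n_looks_target",
        main_predictor=DEM,
        control_predictors=CONTROLS,
        structure="diagonal",
        random_slope_terms=[DEM, "condition"],
    )
    covered = 0
    n_used = 0
    for s in _rep_seeds(seed, n_reps):
        table, truth = generate_response_table(effect, seed=int(s))
        res = fit_glmm(spec, table, test_terms=[])
        if not res.converged:
            continue
        lo, hi = res.wald_ci(DEM, level=level)
        covered += lo <= truth["beta_dem"] <= hi
        n_used += 1
    return {"coverage": covered / n_used, "n_reps": n_used, "n_rows": len(table)}


def sign_recovery_study(
    n_reps: int = 100, seed: int = 0, effect: EffectSpec | None = None
) -> dict:
    """Fraction of replicates in which the fitted demonstrator-count
    coefficient carries the generating sign."""
    effect = EffectSpec() if effect is None else effect
    spec = GlmmSpec(
        family="poisson",
        response="n_looks_target",
        main_predictor=DEM,
        control_predictors=CONTROLS,
        structure="intercept",
        random_slopes=False,
    )
    right = 0
    for s in _rep_seeds(seed, n_reps):
        table, truth = generate_response_table(effect, seed=int(s))
        res = fit_glmm(spec, table, test_terms=[])
        right += np.sign(res.coef(DEM)) == np.sign(truth["beta_dem"])
    return {"sign_agreement": right / n_reps, "n_reps": n_reps}


def type_i_error_study(
    n_reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    n_individuals: int = 40,
    n_presentations: int = 8,
) -> dict:
    """Rejection rate of the demonstrator-count LRT when the generating
    effect is zero (Poisson family, intercept-only random structure)."""
    effect = EffectSpec(
        beta_dem=0.0,
        re_slope_sd=0.0,
        n_individuals=n_individuals,
        n_presentations=n_presentations,
    )
    spec = GlmmSpec(
        family="poisson",
        response="n_looks_target",
        main_predictor=DEM,
        control_predictors=["condition"],
        structure="intercept",
        random_slopes=False,
    )
    rejections = 0
    n_used = 0
    for s in _rep_seeds(seed, n_reps):
        table, _ = generate_response_table(effect, seed=int(s))
        res = fit_glmm(spec, table)
        if not res.converged:
            continue
        rejections += float(res.tests["p"].iloc[0]) < alpha
        n_used += 1
    return {"type_i_error": rejections / n_used, "n_reps": n_used, "alpha": alpha}


def aic_linear_vs_quadratic_study(
    n_reps: int = 200, seed: int = 0, effect: EffectSpec | None = None
) -> dict:
    """Fraction of linear-truth replicates in which AIC prefers the linear
    over the quadratic demonstrator-count model.

    Linear truth means the *marginal* mean is linear in the z-scored count:
    the generating quadratic term is zero and the per-individual random
    slope on the count is switched off (marginalizing a lognormal random
    slope would itself induce a quadratic term of size sigma^2 z^2 / 2)."""
    effect = EffectSpec(beta_dem2=0.0, re_slope_sd=0.0) if effect is None else effect
    base = dict(
        family="poisson",
        response="n_looks_target",
        main_predictor=DEM,
        control_predictors=["condition"],
        structure="intercept",
        random_slopes=False,
    )
    linear_wins = 0
    for s in _rep_seeds(seed, n_reps):
        table, _ = generate_response_table(effect, seed=int(s))
        lin = fit_glmm(GlmmSpec(**base), table, test_terms=[])
        quad = fit_glmm(GlmmSpec(**base, quadratic=True), table, test_terms=[])
        linear_wins += compare_models(lin, quad)["preferred"] == "a"
    return {"linear_preferred": linear_wins / n_reps, "n_reps": n_reps}
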