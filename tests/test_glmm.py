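import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from pigeongaze.glmm import GlmmError, fit_laplace_glmm
from pigeongaze.stats import (
    GlmmSpec,
    StatsError,
    back_transform,
    compare_models,
    diagnostics,
    fit_glmm,
    simulate_ci,
    zscore_predictors,
)
from pigeongaze.synthetic import EffectSpec, generate_response_table


@pytest.fixture(scope="module")
def small_table():
    table, truth = generate_response_table(
        EffectSpec(n_individuals=25, n_presentations=12), seed=5
    )
    return table, truth


BASE_SPEC = dict(
    family="poisson",
    response="n_looks_target",
    main_predictor="n_actual_demonstrators",
    control_predictors=["condition"],
    structure="intercept",
    random_slopes=False,
)


class TestZScore:
    def test_three_point_column(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out, scaling = zscore_predictors(df, ["x"])
        assert np.allclose(out["x"], [-1.0, 0.0, 1.0])
        assert scaling["x"] == (2.0, 1.0)

    def test_constant_column_raises(self):
        with pytest.raises(StatsError, match="zero-variance"):
            zscore_predictors(pd.DataFrame({"x": [2.0, 2.0, 2.0]}), ["x"])

    def test_round_trip(self):
        df = pd.DataFrame({"x": [4.0, 9.0, 1.0, 7.0]})
        out, scaling = zscore_predictors(df, ["x"])
        assert np.allclose(back_transform(out["x"].to_numpy(), scaling["x"]), df["x"])


class TestEngine:
    def test_matches_glm_at_zero_variance_boundary(self, small_table):
        """With the random-effect scale pinned at ~0 the Laplace GLMM
        log-likelihood equals the ordinary GLM's."""
        import statsmodels.api as sm

        from pigeongaze.glmm import _Problem, _lam_from_theta, _pirls
        from pigeongaze.stats import build_design

        table, _ = small_table
        X, names, y, df, _ = build_design(table, GlmmSpec(**BASE_SPEC))
        prob = _Problem(y, X, df["observer_id"].to_numpy(), None, "poisson")
        lam = _lam_from_theta(np.array([1e-12]), 1, "intercept")
        _, _, ll, _, _ = _pirls(
            prob, lam, prob.start_beta(), np.zeros((prob.G, 1)), max_iter=200, tol=1e-13
        )
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert ll == pytest.approx(glm.llf, abs=1e-6)

    @pytest.mark.parametrize("family,response", [
        ("poisson", "n_looks_target"),
        ("binomial", "looked_target"),
    ])
    def test_against_lme4_reference(self, tmp_path, small_table, family, response):
        """Independent oracle: lme4's Laplace fit of the same model on the
        same table agrees on slopes, log-likelihood and the LRT."""
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        table, _ = small_table
        csv = tmp_path / "tab.csv"
        table.to_csv(csv, index=False)
        spec = GlmmSpec(**{**BASE_SPEC, "family": family, "response": response})
        res = fit_glmm(spec, table)
        script = tmp_path / "ref.R"
        script.write_text(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv('{csv}')
            d$zdem <- scale(d$n_actual_demonstrators)
            d$cond <- as.numeric(d$condition == 'test')
            m <- glmer({response} ~ zdem + cond + (1|observer_id), data=d, family={family})
            mr <- glmer({response} ~ cond + (1|observer_id), data=d, family={family})
            cat(fixef(m), logLik(m), AIC(m), 2*(logLik(m)-logLik(mr)), sep=',')
            """
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        vals = [float(v) for v in out.stdout.strip().split(",")]
        r_beta, r_ll, r_aic, r_chi2 = np.array(vals[:3]), vals[3], vals[4], vals[5]
        py_beta = np.array([res.coef("intercept"), res.coef("n_actual_demonstrators"), res.coef("condition")])
        assert np.allclose(py_beta[1:], r_beta[1:], atol=0.05)
        assert abs(py_beta[0] - r_beta[0]) < 0.1
        assert res.fit.loglike == pytest.approx(r_ll, abs=0.2)
        assert res.aic == pytest.approx(r_aic, abs=0.5)
        assert float(res.tests["chi2"].iloc[0]) == pytest.approx(r_chi2, abs=0.1)

    def test_all_zero_response_flagged_not_crashed(self):
        table = pd.DataFrame(
            {
                "observer_id": ["a", "b"] * 20,
                "n_actual_demonstrators": np.tile(np.arange(4), 10),
                "condition": ["test", "control"] * 20,
                "n_looks_target": 0,
            }
        )
        res = fit_glmm(GlmmSpec(**BASE_SPEC), table, test_terms=[])
        assert not res.converged

    def test_bad_family_rejected(self):
        with pytest.raises(GlmmError):
            fit_laplace_glmm([0.5, 1.2], np.ones((2, 1)), ["a", "b"], "binomial")

    def test_lrt_statistics_are_valid(self, small_table):
        table, _ = small_table
        res = fit_glmm(GlmmSpec(**BASE_SPEC), table)
        chi2 = float(res.tests["chi2"].iloc[0])
        p = float(res.tests["p"].iloc[0])
        assert chi2 >= 0.0
        assert 0.0 < p <= 1.0

    def test_row_order_invariance(self, small_table):
        """Shuffling row order changes no reported statistic beyond 1e-6."""
        table, _ = small_table
        res1 = fit_glmm(GlmmSpec(**BASE_SPEC), table)
        shuffled = table.sample(frac=1.0, random_state=13).reset_index(drop=True)
        res2 = fit_glmm(GlmmSpec(**BASE_SPEC), shuffled)
        assert np.allclose(res1.fit.beta, res2.fit.beta, atol=1e-6)
        assert res1.fit.loglike == pytest.approx(res2.fit.loglike, abs=1e-6)
        assert float(res1.tests["chi2"].iloc[0]) == pytest.approx(
            float(res2.tests["chi2"].iloc[0]), abs=1e-6
        )

    def test_wald_option(self, small_table):
        table, _ = small_table
        res = fit_glmm(GlmmSpec(**BASE_SPEC), table, test_method="wald")
        b = res.coef("n_actual_demonstrators")
        s = res.se("n_actual_demonstrators")
        assert float(res.tests["chi2"].iloc[0]) == pytest.approx((b / s) ** 2)

    def test_fallback_ladder_records_path(self, small_table):
        table, _ = small_table
        spec = GlmmSpec(
            **{**BASE_SPEC, "structure": "diagonal", "random_slopes": True,
               "random_slope_terms": ["n_actual_demonstrators"]},
        )
        res = fit_glmm(spec, table, test_terms=[])
        assert res.fallback_path[0] == "diagonal"
        assert res.fit.structure in ("diagonal", "intercept")


def test_fitted_sign_matches_generating_sign():
    """At the combined-data scale the fitted demonstrator-count coefficient
    carries the generating sign in at least 95% of replicates."""
    from pigeongaze.recovery import sign_recovery_study

    out = sign_recovery_study(n_reps=50, seed=77)
    assert out["sign_agreement"] >= 0.95


class TestCompareModels:
    def test_identical_models_delta_zero(self, small_table):
        table, _ = small_table
        a = fit_glmm(GlmmSpec(**BASE_SPEC), table, test_terms=[])
        b = fit_glmm(GlmmSpec(**BASE_SPEC), table, test_terms=[])
        cmp = compare_models(a, b)
        assert cmp["delta_aic"] == pytest.approx(0.0, abs=1e-6)

    def test_mismatched_rows_rejected(self, small_table):
        table, _ = small_table
        a = fit_glmm(GlmmSpec(**BASE_SPEC), table, test_terms=[])
        b = fit_glmm(GlmmSpec(**BASE_SPEC), table.iloc[:100], test_terms=[])
        with pytest.raises(StatsError):
            compare_models(a, b)


class TestSimulateCI:
    def test_degenerate_covariance_collapses_band(self, small_table):
        table, _ = small_table
        res = fit_glmm(GlmmSpec(**BASE_SPEC), table, test_terms=[])
        res.fit.cov_beta = np.zeros_like(res.fit.cov_beta)
        band = simulate_ci(res, "condition", [0.0, 1.0], n_draws=500,
                           rng=np.random.default_rng(0))
        assert np.allclose(band.ci_low, band.predicted, atol=1e-12)
        assert np.allclose(band.ci_high, band.predicted, atol=1e-12)

    def test_band_widens_with_coefficient_se(self, small_table):
        table, _ = small_table
        res = fit_glmm(GlmmSpec(**BASE_SPEC), table, test_terms=[])
        narrow = simulate_ci(res, "condition", [1.0], n_draws=4000,
                             rng=np.random.default_rng(1))
        res.fit.cov_beta = res.fit.cov_beta * 4.0
        wide = simulate_ci(res, "condition", [1.0], n_draws=4000,
                           rng=np.random.default_rng(1))
        assert (wide.ci_high - wide.ci_low).iloc[0] > (narrow.ci_high - narrow.ci_low).iloc[0]

    def test_refuses_non_converged_fit(self):
        table = pd.DataFrame(
            {
                "observer_id": ["a", "b"] * 20,
                "n_actual_demonstrators": np.tile(np.arange(4), 10),
                "condition": ["test", "control"] * 20,
                "n_looks_target": 0,
            }
        )
        res = fit_glmm(GlmmSpec(**BASE_SPEC), table, test_terms=[])
        with pytest.raises(StatsError):
            simulate_ci(res, "condition", [0.0, 1.0])


class TestDiagnostics:
    def test_overdispersion_near_one_for_true_poisson(self, small_table):
        table, _ = small_table
        res = fit_glmm(GlmmSpec(**BASE_SPEC), table, test_terms=[])
        d = diagnostics(res)
        assert 0.7 < d["overdispersion"] < 1.3

    def test_orthogonal_predictors_have_unit_vif(self):
        rng = np.random.default_rng(2)
        n = 400
        table = pd.DataFrame(
            {
                "observer_id": np.repeat([f"i{k}" for k in range(20)], 20),
                "n_actual_demonstrators": rng.integers(0, 9, n),
                "condition": rng.choice(["test", "control"], n),
                "n_looks_target": rng.poisson(1.0, n),
            }
        )
        res = fit_glmm(GlmmSpec(**BASE_SPEC), table, test_terms=[])
        vif = diagnostics(res)["vif"]
        assert (vif < 1.1).all()

    def test_planted_outlier_individual_has_largest_cooks_distance(self):
        rng = np.random.default_rng(4)
        ids = [f"i{k}" for k in range(12)]
        n_per = 25
        rows = []
        for i, ind in enumerate(ids):
            lam = 8.0 if i == 0 else 1.0  # one individual with inflated counts
            for _ in range(n_per):
                rows.append(
                    {
                        "observer_id": ind,
                        "n_actual_demonstrators": int(rng.integers(0, 9)),
                        "condition": rng.choice(["test", "control"]),
                        "n_looks_target": int(rng.poisson(lam)),
                    }
                )
        res = fit_glmm(GlmmSpec(**BASE_SPEC), pd.DataFrame(rows), test_terms=[])
        cooks = diagnostics(res, cooks=True)["cooks_distance"]
        assert cooks.idxmax() == "i0"
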