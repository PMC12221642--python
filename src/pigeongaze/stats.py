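"""Mixed-model analysis of the presentation tables.

Responses are either binary (did the observer look at the target during the
presentation: binomial family, logit link) or counts (number of looks:
Poisson family, log link). The main predictor is the condition (control = 0,
test = 1) or the number of actual demonstrators; control predictors are the
trial number, presentation number, presentation location and (combined
analyses only) the experiment id. All numeric predictors are z-scored on
the modeled rows. The random structure is per-individual: intercept plus
random slopes for all fixed effects, with a documented fallback ladder on
non-convergence (correlated -> uncorrelated -> intercept-only), the step
taken recorded in the result.

Each main predictor's chi-square(1) is a likelihood-ratio test of the full
model against the model dropping that fixed effect (identical random
structure); a Wald chi-square is available as an option. Confidence bands
for figures come from simulating fixed-effect vectors from their asymptotic
normal distribution (10,000 draws by default) and predicting on the
response scale with the other variables held at their means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glmm import GlmmError, GlmmFit, fit_laplace_glmm, pearson_residuals

FALLBACK_LADDER = ("correlated", "diagonal", "intercept")


class StatsError(ValueError):
    pass


# --------------------------------------------------------------- z-scoring


def zscore_predictors(
    table: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Replace each column by (x - mean) / sd (ddof=1) computed on the
    modeled rows; the scaling record allows back-transformation."""
    table = table.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        mu = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise StatsError(f"zero-variance predictor column: {col!r}")
        table[col] = (x - mu) / sd
        scaling[col] = (mu, sd)
    return table, scaling


def back_transform(values: np.ndarray, scaling: tuple[float, float]) -> np.ndarray:
    mu, sd = scaling
    return np.asarray(values) * sd + mu


# ------------------------------------------------------------- model spec


@dataclass
class GlmmSpec:
    """Declarative model specification against a presentation table."""

    family: str  # "binomial" | "poisson"
    response: str  # e.g. looked_target | n_looks_target | first_look_target
    main_predictor: str  # condition | n_actual_demonstrators | n_demonstrators
    quadratic: bool = False
    control_predictors: list[str] = field(default_factory=list)
    group: str = "observer_id"
    random_slopes: bool = True
    random_slope_terms: list[str] | None = None  # None = slopes for all fixed effects
    structure: str = "correlated"  # starting rung of the fallback ladder

    def __post_init__(self) -> None:
        if self.quadratic and self.main_predictor == "condition":
            raise StatsError("quadratic term requires a count main predictor")


@dataclass
class GlmmResult:
    """Fitted model plus the tests and bookkeeping the reports need."""

    spec: GlmmSpec
    fit: GlmmFit
    tests: pd.DataFrame  # term, chi2, df, p
    scaling: dict[str, tuple[float, float]]
    fallback_path: list[str]
    # modeled data kept for diagnostics / CI simulation
    y: np.ndarray = field(repr=False, default=None)
    X: np.ndarray = field(repr=False, default=None)
    groups: np.ndarray = field(repr=False, default=None)
    re_design: np.ndarray = field(repr=False, default=None)

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def converged(self) -> bool:
        return self.fit.converged

    def coef(self, term: str) -> float:
        return float(self.fit.beta[self.fit.exog_names.index(term)])

    def se(self, term: str) -> float:
        return float(self.fit.se[self.fit.exog_names.index(term)])

    def wald_ci(self, term: str, level: float = 0.95) -> tuple[float, float]:
        z = sps.norm.ppf(0.5 + level / 2.0)
        b, s = self.coef(term), self.se(term)
        return b - z * s, b + z * s

    def report(self) -> str:
        lines = [
            f"{self.spec.family} GLMM: {self.spec.response} ~ "
            f"{self.spec.main_predictor}"
            + (" + quadratic" if self.spec.quadratic else "")
            + (f" + {' + '.join(self.spec.control_predictors)}" if self.spec.control_predictors else ""),
            f"random structure: {self.fit.structure} "
            f"(fallback path: {' -> '.join(self.fallback_path)})",
            f"n_obs = {self.fit.n_obs}, n_individuals = {self.fit.n_groups}, "
            f"AIC = {self.fit.aic:.1f}, converged = {self.fit.converged}",
        ]
        for name, b, s in zip(self.fit.exog_names, self.fit.beta, self.fit.se):
            lines.append(f"  {name:<28s} beta = {b:+.3f}  se = {s:.3f}")
        for _, r in self.tests.iterrows():
            lines.append(
                f"  test {r['term']:<23s} chi2({int(r['df'])}) = {r['chi2']:.3f}, "
                f"p = {r['p']:.4f}"
            )
        return "\n".join(lines)


# ------------------------------------------------------ design construction

CONDITION_CODES = {"control": 0.0, "test": 1.0}


def _encode_column(table: pd.DataFrame, col: str) -> tuple[np.ndarray, list[str]]:
    """Numeric columns pass through; categoricals become 0/1 dummies
    (first sorted level dropped). Condition is coded control=0, test=1."""
    s = table[col]
    if col == "condition":
        bad = set(s) - set(CONDITION_CODES)
        if bad:
            raise StatsError(f"unknown condition labels: {sorted(bad)}")
        return s.map(CONDITION_CODES).to_numpy(dtype=float)[:, None], ["condition"]
    if pd.api.types.is_numeric_dtype(s):
        return s.to_numpy(dtype=float)[:, None], [col]
    levels = sorted(map(str, s.unique()))
    cols = []
    names = []
    for lvl in levels[1:]:
        cols.append((s.astype(str) == lvl).to_numpy(dtype=float))
        names.append(f"{col}[{lvl}]")
    if not cols:
        raise StatsError(f"categorical column {col!r} has a single level")
    return np.column_stack(cols), names


def build_design(
    table: pd.DataFrame, spec: GlmmSpec
) -> tuple[np.ndarray, list[str], np.ndarray, pd.DataFrame, dict]:
    """Build (X, names, y, z-scored table, scaling) for a spec.

    Numeric predictors (the main count predictor and numeric controls) are
    z-scored on the modeled rows; the quadratic term is the square of the
    z-scored main predictor.
    """
    df = table.copy()
    numeric = [
        c
        for c in [spec.main_predictor, *spec.control_predictors]
        if c != "condition" and pd.api.types.is_numeric_dtype(df[c])
    ]
    df, scaling = zscore_predictors(df, numeric)
    blocks = [np.ones((len(df), 1))]
    names = ["intercept"]
    for col in [spec.main_predictor, *spec.control_predictors]:
        b, n = _encode_column(df, col)
        blocks.append(b)
        names.extend(n)
    if spec.quadratic:
        z = df[spec.main_predictor].to_numpy(dtype=float)
        blocks.append((z**2)[:, None])
        names.append(f"{spec.main_predictor}^2")
    X = np.column_stack(blocks)
    y = df[spec.response].to_numpy(dtype=float)
    return X, names, y, df, scaling


# -------------------------------------------------------------- model fit


def _fit_ladder(
    y, X, groups, family, re_design, start: str, names
) -> tuple[GlmmFit, list[str]]:
    ladder = FALLBACK_LADDER[FALLBACK_LADDER.index(start) :]
    if re_design is None or re_design.shape[1] == 1:
        ladder = ("intercept",)
    path: list[str] = []
    fit = None
    for structure in ladder:
        rd = re_design if structure != "intercept" else None
        fit = fit_laplace_glmm(
            y, X, groups, family, re_design=rd, structure=structure, exog_names=names
        )
        path.append(structure)
        if fit.converged:
            break
    return fit, path


def fit_glmm(
    spec: GlmmSpec,
    table: pd.DataFrame,
    test_terms: list[str] | None = None,
    test_method: str = "lrt",
) -> GlmmResult:
    """Fit the specified mixed model and test its main predictor(s).

    ``test_terms`` defaults to the main predictor (plus the quadratic term
    when present). With ``test_method="lrt"`` each term's chi-square(1) is a
    likelihood-ratio test against the model without that fixed effect,
    refitted with the identical random structure; ``"wald"`` uses the Wald
    statistic (beta/se)^2 instead.
    """
    if spec.group not in table.columns:
        raise StatsError(f"grouping column {spec.group!r} missing")
    if table[spec.group].nunique() < 2:
        raise GlmmError("need >= 2 individuals")
    X, names, y, df, scaling = build_design(table, spec)
    groups = df[spec.group].to_numpy()
    if not spec.random_slopes:
        re_design = None
    elif spec.random_slope_terms is None:
        re_design = X.copy()
    else:
        cols = [0] + [names.index(t) for t in spec.random_slope_terms]
        re_design = X[:, cols]
    fit, path = _fit_ladder(y, X, groups, spec.family, re_design, spec.structure, names)

    if test_terms is None:
        test_terms = [n for n in names if n.startswith(spec.main_predictor)]
        test_terms = (
            [t for t in test_terms if not t.endswith("^2")][-1:]
            + ([f"{spec.main_predictor}^2"] if spec.quadratic else [])
        )
    rows = []
    for term in test_terms:
        if term not in names:
            raise StatsError(f"unknown test term {term!r}")
        if test_method == "wald":
            b, s = fit.beta[names.index(term)], fit.se[names.index(term)]
            chi2 = (b / s) ** 2 if s > 0 else np.nan
        else:
            keep = [i for i, n in enumerate(names) if n != term]
            red_names = [names[i] for i in keep]
            red_fit, _ = _fit_ladder(
                y, X[:, keep], groups, spec.family, re_design, fit.structure, red_names
            )
            chi2 = max(0.0, 2.0 * (fit.loglike - red_fit.loglike))
        p = float(sps.chi2.sf(chi2, 1)) if np.isfinite(chi2) else np.nan
        rows.append({"term": term, "chi2": float(chi2), "df": 1, "p": p})
    tests = pd.DataFrame(rows, columns=["term", "chi2", "df", "p"])
    return GlmmResult(
        spec=spec,
        fit=fit,
        tests=tests,
        scaling=scaling,
        fallback_path=path,
        y=y,
        X=X,
        groups=groups,
        re_design=re_design,
    )


# --------------------------------------------------------- model comparison


def compare_models(result_a: GlmmResult, result_b: GlmmResult) -> dict:
    """AIC comparison of two fits on the same response rows."""
    if result_a.fit.n_obs != result_b.fit.n_obs:
        raise StatsError("models fitted to different numbers of rows")
    delta = result_a.aic - result_b.aic
    return {
        "aic_a": result_a.aic,
        "aic_b": result_b.aic,
        "delta_aic": delta,
        "preferred": "a" if delta <= 0 else "b",
    }


# --------------------------------------------------------- simulation CIs


def simulate_ci(
    result: GlmmResult,
    term: str,
    values: np.ndarray,
    n_draws: int = 10_000,
    rng: np.random.Generator | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Simulation-based confidence band for predicted responses.

    Fixed-effect vectors are drawn from N(beta_hat, cov_beta); predictions
    are made on the response scale at each value of ``term`` with every
    other design column held at its mean. Returns the point prediction and
    the percentile band (2.5th/97.5th at the default level).
    """
    if not result.converged:
        raise StatsError("refusing to simulate from a non-converged fit")
    rng = np.random.default_rng() if rng is None else rng
    names = result.fit.exog_names
    if term not in names:
        raise StatsError(f"unknown term {term!r}")
    j = names.index(term)
    base = result.X.mean(axis=0)
    cov = result.fit.cov_beta
    # guard: a degenerate (zero) covariance collapses the band to the point
    if np.all(np.abs(cov) < 1e-300):
        draws = np.tile(result.fit.beta, (n_draws, 1))
    else:
        draws = rng.multivariate_normal(result.fit.beta, cov, size=n_draws, method="svd")
    inv_link = np.exp if result.spec.family == "poisson" else lambda e: 1 / (1 + np.exp(-e))
    lo_q, hi_q = 50 * (1 - level), 50 * (1 + level)
    rows = []
    values = np.atleast_1d(values)
    for v in values:
        x = base.copy()
        x[j] = v
        quad = f"{term}^2"
        if quad in names:
            x[names.index(quad)] = v**2
        eta = draws @ x
        pred = inv_link(np.clip(eta, -30, 30))
        point = float(inv_link(np.clip(result.fit.beta @ x, -30, 30)))
        rows.append(
            {
                "value": float(v),
                "predicted": point,
                "ci_low": float(np.percentile(pred, lo_q)),
                "ci_high": float(np.percentile(pred, hi_q)),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------- diagnostics


def overdispersion(result: GlmmResult) -> float:
    """Pearson chi-square over residual df (conditional residuals);
    values near 1 indicate the Poisson variance assumption holds."""
    resid = pearson_residuals(
        result.fit, result.y, result.X, result.groups, result.re_design
        if result.fit.structure != "intercept"
        else None,
    )
    df = result.fit.n_obs - len(result.fit.beta)
    return float(np.sum(resid**2) / df)


def vif_table(result: GlmmResult) -> pd.Series:
    """Variance inflation factors of the fixed-effect columns (intercept
    excluded); values near 1 mean no collinearity."""
    names = result.fit.exog_names
    keep = [i for i, n in enumerate(names) if n != "intercept"]
    X = result.X[:, keep]
    out = {}
    for k, i in enumerate(keep):
        others = np.delete(X, k, axis=1)
        a = np.column_stack([np.ones(len(X)), others])
        coef, *_ = np.linalg.lstsq(a, X[:, k], rcond=None)
        resid = X[:, k] - a @ coef
        tot = np.sum((X[:, k] - X[:, k].mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / tot if tot > 0 else 0.0
        out[names[i]] = 1.0 / max(1.0 - r2, 1e-12)
    return pd.Series(out, name="vif")


def cooks_distances(result: GlmmResult) -> pd.Series:
    """Leave-one-individual-out Cook's distance per individual.

    D_g = (beta - beta_(-g))' Cov(beta)^-1 (beta - beta_(-g)) / p; large
    values flag individuals that drag the fixed-effect estimates.
    """
    if not result.converged:
        raise StatsError("diagnostics require a converged fit")
    beta = result.fit.beta
    p = len(beta)
    cov_inv = np.linalg.pinv(result.fit.cov_beta)
    out = {}
    labels = result.fit.group_labels
    for g in labels:
        keep = result.groups != g
        rd = result.re_design[keep] if result.re_design is not None else None
        fit_g, _ = _fit_ladder(
            result.y[keep],
            result.X[keep],
            result.groups[keep],
            result.spec.family,
            rd,
            result.fit.structure,
            result.fit.exog_names,
        )
        d = beta - fit_g.beta
        out[g] = float(d @ cov_inv @ d / p)
    return pd.Series(out, name="cooks_distance")


def diagnostics(result: GlmmResult, cooks: bool = False) -> dict:
    """Bundle of the model checks: overdispersion (Poisson only), VIFs and
    optionally the leave-one-individual-out Cook's distances."""
    out: dict = {"vif": vif_table(result)}
    if result.spec.family == "poisson":
        out["overdispersion"] = overdispersion(result)
    if cooks:
        out["cooks_distance"] = cooks_distances(result)
    return out
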