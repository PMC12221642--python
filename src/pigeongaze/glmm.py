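"""Maximum-likelihood generalized linear mixed models via the Laplace
approximation.

Model: responses y_i from a Poisson (log link) or Bernoulli (logit link)
family with linear predictor

    eta = X beta + Z b,    b_g ~ N(0, Sigma)  independently per group g,

where Z holds per-group copies of the random-effect design (intercept and
optional slopes). Sigma is parameterized through its relative Cholesky
factor Lambda (Sigma = Lambda Lambda'), with spherical random effects u,
b = Lambda u, u ~ N(0, I).

Fitting follows the standard penalized iteratively reweighted least squares
(PIRLS) scheme: for a candidate Lambda, (beta, u) jointly solve a penalized
weighted least-squares problem at each IRLS step; the Laplace-approximate
profiled deviance

    -2 [ sum log p(y | eta_hat) - ||u_hat||^2 / 2
         - log det(Lambda' Z' W Z Lambda + I) / 2 ]

is then minimized over the free elements of Lambda (diagonal constrained
nonnegative, so a variance component can vanish at the boundary). The
penalized system is block-diagonal in the per-group random effects, so each
IRLS step solves a p x p Schur-complement system plus G batched q x q
blocks; cost is linear in the number of observations. Fixed-effect standard
errors come from the beta block of the inverse penalized information matrix
at the optimum.

Three random-effect structures are supported: ``correlated`` (full lower
triangular Lambda), ``diagonal`` (independent random effects) and
``intercept`` (random intercept only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import gammaln

FAMILIES = ("poisson", "binomial")
ETA_CLIP = 30.0
BETA_DEGENERATE = 15.0  # |beta| beyond this signals separation/degeneracy
THETA_BOUND = 25.0


class GlmmError(ValueError):
    pass


def _check_family(family: str) -> str:
    if family not in FAMILIES:
        raise GlmmError(f"family must be one of {FAMILIES}, got {family!r}")
    return family


def _loglik(y: np.ndarray, eta: np.ndarray, family: str) -> float:
    if family == "poisson":
        return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1)))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _mu_w(eta: np.ndarray, family: str) -> tuple[np.ndarray, np.ndarray]:
    if family == "poisson":
        mu = np.exp(eta)
        return mu, mu
    mu = 1.0 / (1.0 + np.exp(-eta))
    return mu, mu * (1.0 - mu)


@dataclass
class GlmmFit:
    """A fitted mixed model."""

    family: str
    exog_names: list[str]
    beta: np.ndarray
    cov_beta: np.ndarray  # (p, p) asymptotic covariance of beta
    lam: np.ndarray  # (q, q) lower-triangular relative Cholesky factor
    structure: str
    loglike: float
    aic: float
    converged: bool
    n_obs: int
    n_groups: int
    n_theta: int
    u: np.ndarray = field(repr=False, default=None)  # (G, q) spherical modes
    group_labels: list = field(repr=False, default=None)
    re_names: list[str] = field(default=None)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_beta), 0.0, None))

    @property
    def sigma(self) -> np.ndarray:
        """Random-effect covariance matrix Sigma = Lambda Lambda'."""
        return self.lam @ self.lam.T

    def params_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"estimate": self.beta, "se": self.se}, index=self.exog_names
        )


class _Problem:
    """Pre-arranged data for one model."""

    def __init__(self, y, X, groups, re_design, family):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.asarray(X, dtype=float)
        self.family = _check_family(family)
        n = self.y.shape[0]
        if self.X.shape[0] != n:
            raise GlmmError("X and y row mismatch")
        labels, codes = np.unique(np.asarray(groups), return_inverse=True)
        self.group_labels = list(labels)
        self.codes = codes
        self.G = len(labels)
        if self.G < 2:
            raise GlmmError("need >= 2 groups (individuals)")
        self.Zre = (
            np.ones((n, 1)) if re_design is None else np.asarray(re_design, dtype=float)
        )
        self.q = self.Zre.shape[1]
        self.p = self.X.shape[1]
        if self.family == "binomial" and not np.all(np.isin(self.y, (0.0, 1.0))):
            raise GlmmError("binomial family requires 0/1 responses")
        if self.family == "poisson" and (
            np.any(self.y < 0) or np.any(self.y != np.round(self.y))
        ):
            raise GlmmError("poisson family requires nonnegative integer responses")

    def eta(self, lam: np.ndarray, beta: np.ndarray, u: np.ndarray) -> np.ndarray:
        zlam = self.Zre @ lam  # (n, q)
        return np.clip(
            self.X @ beta + np.sum(zlam * u[self.codes], axis=1), -ETA_CLIP, ETA_CLIP
        )

    def start_beta(self) -> np.ndarray:
        beta = np.zeros(self.p)
        ybar = float(np.clip(self.y.mean(), 1e-3, None))
        if self.family == "poisson":
            eta0 = np.log(ybar)
        else:
            ybar = min(max(ybar, 1e-3), 1 - 1e-3)
            eta0 = np.log(ybar / (1 - ybar))
        const_cols = np.where(np.ptp(self.X, axis=0) == 0)[0]
        if const_cols.size:
            c = const_cols[0]
            beta[c] = eta0 / self.X[0, c]
        return beta

    def grouped_blocks(self, w: np.ndarray):
        """S (G, q, q) = per-group Zre' W Zre and the helper for X' W Zre."""
        q, G, codes = self.q, self.G, self.codes
        S = np.empty((G, q, q))
        for i in range(q):
            for j in range(i + 1):
                v = np.bincount(codes, weights=w * self.Zre[:, i] * self.Zre[:, j], minlength=G)
                S[:, i, j] = v
                S[:, j, i] = v
        return S

    def grouped_xtwz(self, w: np.ndarray) -> np.ndarray:
        """C (G, p, q) with C_g = X_g' W_g Zre_g."""
        p, q, G, codes = self.p, self.q, self.G, self.codes
        C = np.empty((G, p, q))
        for a in range(p):
            for j in range(q):
                C[:, a, j] = np.bincount(
                    codes, weights=w * self.X[:, a] * self.Zre[:, j], minlength=G
                )
        return C

    def grouped_vec(self, w: np.ndarray, r: np.ndarray) -> np.ndarray:
        """(G, q) with row g = Zre_g' W_g r_g."""
        q, G, codes = self.q, self.G, self.codes
        out = np.empty((G, q))
        for j in range(q):
            out[:, j] = np.bincount(codes, weights=w * r * self.Zre[:, j], minlength=G)
        return out


def _pirls(
    prob: _Problem,
    lam: np.ndarray,
    beta0: np.ndarray,
    u0: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-9,
):
    """Penalized IRLS at fixed Lambda.

    Returns (beta, u, laplace_ll, converged, cov_beta) with u the (G, q)
    spherical random-effect modes and cov_beta the beta block of the inverse
    penalized information matrix.
    """
    y, X = prob.y, prob.X
    p, q, G = prob.p, prob.q, prob.G
    beta = beta0.copy()
    u = u0.copy()

    def pdev(beta, u):
        eta = prob.eta(lam, beta, u)
        return -2.0 * _loglik(y, eta, prob.family) + float(np.sum(u * u)), eta

    dev, eta = pdev(beta, u)
    converged = False
    cov_beta = np.full((p, p), np.nan)
    eye_q = np.eye(q)
    for _ in range(max_iter):
        mu, w = _mu_w(eta, prob.family)
        w = np.clip(w, 1e-10, None)
        z = eta + (y - mu) / w
        # blocks of the penalized normal equations
        S = prob.grouped_blocks(w)  # (G, q, q)
        D = lam.T @ S @ lam + eye_q  # (G, q, q)
        C = prob.grouped_xtwz(w) @ lam  # (G, p, q)
        xtwx = X.T @ (X * w[:, None])
        xtwz = X.T @ (w * z)
        ru = prob.grouped_vec(w, z) @ lam  # (G, q)
        Dinv = np.linalg.inv(D)
        CDi = C @ Dinv  # (G, p, q)
        schur = xtwx - np.einsum("gpq,grq->pr", CDi, C)
        rhs = xtwz - np.einsum("gpq,gq->p", CDi, ru)
        try:
            beta_new = np.linalg.solve(schur, rhs)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(schur, rhs, rcond=None)[0]
        u_new = np.einsum(
            "gqr,gr->gq", Dinv, ru - np.einsum("gpq,p->gq", C, beta_new)
        )
        # step-halving on the penalized deviance
        step = 1.0
        for _ in range(15):
            bt = beta + step * (beta_new - beta)
            ut = u + step * (u_new - u)
            dev_new, eta_new = pdev(bt, ut)
            if dev_new <= dev + 1e-12:
                break
            step *= 0.5
        delta = dev - dev_new
        beta, u, eta = bt, ut, eta_new
        dev = dev_new
        try:
            cov_beta = np.linalg.inv(schur)
        except np.linalg.LinAlgError:
            pass
        if abs(delta) < tol * (abs(dev) + 1.0):
            converged = True
            break
    # Laplace log-likelihood at the mode
    mu, w = _mu_w(eta, prob.family)
    w = np.clip(w, 1e-10, None)
    D = lam.T @ prob.grouped_blocks(w) @ lam + eye_q
    sign, logdet = np.linalg.slogdet(D)
    if np.any(sign <= 0):
        return beta, u, -np.inf, False, cov_beta
    ll = _loglik(y, eta, prob.family) - 0.5 * float(np.sum(u * u)) - 0.5 * float(
        logdet.sum()
    )
    return beta, u, ll, converged, cov_beta


def _lam_from_theta(theta: np.ndarray, q: int, structure: str) -> np.ndarray:
    lam = np.zeros((q, q))
    if structure == "intercept" or q == 1:
        lam[0, 0] = theta[0]
    elif structure == "diagonal":
        lam[np.diag_indices(q)] = theta
    else:
        lam[np.tril_indices(q)] = theta
    return lam


def _theta_init(q: int, structure: str) -> tuple[np.ndarray, list[tuple]]:
    if structure == "intercept" or q == 1:
        return np.array([1.0]), [(0.0, THETA_BOUND)]
    if structure == "diagonal":
        return np.full(q, 0.5), [(0.0, THETA_BOUND)] * q
    idx = np.tril_indices(q)
    theta = np.zeros(len(idx[0]))
    bounds = []
    for k, (r, c) in enumerate(zip(*idx)):
        if r == c:
            theta[k] = 0.5
            bounds.append((0.0, THETA_BOUND))
        else:
            bounds.append((-THETA_BOUND, THETA_BOUND))
    return theta, bounds


def fit_laplace_glmm(
    y,
    X,
    groups,
    family: str,
    re_design=None,
    structure: str = "intercept",
    exog_names: list[str] | None = None,
    re_names: list[str] | None = None,
) -> GlmmFit:
    """Fit a GLMM by Laplace-approximate maximum likelihood.

    Parameters
    ----------
    y : response vector (0/1 for binomial, counts for poisson).
    X : (n, p) fixed-effect design (include an intercept column).
    groups : length-n group (individual) labels.
    re_design : (n, q) random-effect design per row; default a random
        intercept (column of ones).
    structure : "intercept" | "diagonal" | "correlated".
    """
    if structure == "intercept":
        re_design = None
    prob = _Problem(y, X, groups, re_design, family)
    q = prob.q
    theta, bounds = _theta_init(q, structure)
    state = {"beta": prob.start_beta(), "u": np.zeros((prob.G, q))}

    def objective(th):
        lam = _lam_from_theta(np.atleast_1d(th), q, structure)
        beta, u, ll, conv, _ = _pirls(prob, lam, state["beta"], state["u"])
        if np.isfinite(ll):
            state["beta"], state["u"] = beta, u
            return -2.0 * ll
        return 1e12

    if len(theta) == 1:
        res = optimize.minimize_scalar(
            lambda t: objective([t]),
            bounds=(0.0, THETA_BOUND),
            method="bounded",
            options={"xatol": 1e-5},
        )
        theta_hat = np.array([res.x])
        opt_ok = bool(res.success)
    else:
        res = optimize.minimize(
            objective,
            theta,
            method="Powell",
            bounds=bounds,
            options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 2000},
        )
        theta_hat = np.atleast_1d(res.x)
        opt_ok = bool(res.success)

    lam = _lam_from_theta(theta_hat, q, structure)
    beta, u, ll, pirls_ok, cov_beta = _pirls(prob, lam, state["beta"], state["u"])
    p = prob.p
    degenerate = bool(np.any(np.abs(beta) > BETA_DEGENERATE)) or not np.isfinite(ll)
    converged = bool(opt_ok and pirls_ok and not degenerate)
    n_theta = len(theta_hat)
    aic = -2.0 * ll + 2.0 * (p + n_theta) if np.isfinite(ll) else np.inf
    names = exog_names or [f"x{i}" for i in range(p)]
    return GlmmFit(
        family=prob.family,
        exog_names=list(names),
        beta=beta,
        cov_beta=cov_beta,
        lam=lam,
        structure="intercept" if q == 1 else structure,
        loglike=float(ll),
        aic=float(aic),
        converged=converged,
        n_obs=len(prob.y),
        n_groups=prob.G,
        n_theta=n_theta,
        u=u,
        group_labels=prob.group_labels,
        re_names=re_names,
    )


def pearson_residuals(fit: GlmmFit, y, X, groups, re_design=None) -> np.ndarray:
    """Conditional Pearson residuals (random effects at their modes)."""
    prob = _Problem(y, X, groups, re_design, fit.family)
    eta = prob.eta(fit.lam, fit.beta, fit.u)
    mu, w = _mu_w(eta, fit.family)
    return (prob.y - mu) / np.sqrt(np.clip(w, 1e-10, None))
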