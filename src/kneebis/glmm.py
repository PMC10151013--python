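"""Random-intercept logistic regression fitted by maximum likelihood.

The marginal likelihood integrates the participant-level random intercept out
with adaptive Gauss-Hermite quadrature: each participant's integral is
recentred at the posterior mode of the intercept and rescaled by the local
curvature before applying the Hermite rule.  Inference is Wald (observed
information at the optimum); the intraclass correlation for the binary
outcome uses the latent-threshold residual variance pi^2/3.

Model family
------------
``null``    intercept only (used for the ICC)
``model1``  intercept + metric mean + metric CV + group
``model2``  model1 + mean x group + CV x group interactions
``model3``  intercept + metric mean + metric CV, OA subset only
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from functools import lru_cache

from numpy.polynomial.hermite import hermgauss as _hermgauss
from scipy import optimize, special, stats

from .errors import EstimationError, UsageError

LATENT_RESIDUAL_VAR = math.pi**2 / 3  # logistic latent-threshold convention

@lru_cache(maxsize=8)
def hermgauss(n_nodes: int):
    return _hermgauss(n_nodes)


_METRIC_COLUMNS = {
    "r128": ("plr128_mean", "plr128_cv"),
    "x40": ("plx40_mean", "plx40_cv"),
}

_MODEL_TERMS = {
    "null": ("intercept",),
    "model1": ("intercept", "plz_mean", "plz_cv", "group"),
    "model2": ("intercept", "plz_mean", "plz_cv", "group",
               "plz_mean:group", "plz_cv:group"),
    "model3": ("intercept", "plz_mean", "plz_cv"),
}


@dataclass
class ModelSpec:
    """Which model of the family to fit, on which slice of the data."""

    name: str = "model1"
    metric: str = "r128"            # r128 | x40
    configuration: str = "trans"    # long | trans
    subset: str = "all"             # all | oa_only
    quadrature_nodes: int = 25
    max_iter: int = 500
    tol: float = 1e-9
    pain_col: str = "pain"

    def __post_init__(self):
        if self.name not in _MODEL_TERMS:
            raise UsageError(f"unknown model name {self.name!r}")
        if self.metric not in _METRIC_COLUMNS:
            raise UsageError(f"unknown metric {self.metric!r}")
        if self.name == "model3":
            self.subset = "oa_only"

    @property
    def terms(self) -> tuple[str, ...]:
        return _MODEL_TERMS[self.name]


@dataclass
class ModelFit:
    """Estimates and Wald inference for one fitted model."""

    spec: ModelSpec
    terms: tuple[str, ...]
    coefficients: dict[str, float]
    se: dict[str, float]
    p: dict[str, float]
    odds_ratios: dict[str, float]
    sigma_u2: float
    icc: float
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    quasi_separated: bool = False
    cov: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Table-shaped report: term, estimate, exp(estimate), SE, p."""
        rows = [
            {
                "term": t,
                "estimate": self.coefficients[t],
                "exp_estimate": self.odds_ratios[t],
                "se": self.se[t],
                "p": self.p[t],
            }
            for t in self.terms
        ]
        return pd.DataFrame(rows)


def build_design(data: pd.DataFrame, spec: ModelSpec):
    """Design matrix, outcome, and group codes for one model spec.

    Rows are filtered to the requested electrode configuration (if a
    ``config`` column is present), the requested subset, and complete cases
    for the needed columns.  Degenerate designs raise ``EstimationError``.
    """
    df = data
    if "config" in df.columns:
        df = df[df["config"] == spec.configuration]
    if spec.subset == "oa_only":
        df = df[df["group"] == 1]

    mean_col, cv_col = _METRIC_COLUMNS[spec.metric]
    needed = [spec.pain_col]
    if any(t.startswith("plz_mean") for t in spec.terms):
        needed.append(mean_col)
    if any(t.startswith("plz_cv") for t in spec.terms):
        needed.append(cv_col)
    if "group" in spec.terms:
        needed.append("group")
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    if len(df) == 0:
        raise EstimationError("no usable rows after filtering")

    y = df[spec.pain_col].to_numpy(dtype=float)
    if not (np.any(y == 0) and np.any(y == 1)):
        raise EstimationError("outcome has a single class; cannot fit")

    cols = {}
    for term in spec.terms:
        if term == "intercept":
            cols[term] = np.ones(len(df))
        elif term == "plz_mean":
            cols[term] = df[mean_col].to_numpy(dtype=float)
        elif term == "plz_cv":
            cols[term] = df[cv_col].to_numpy(dtype=float)
        elif term == "group":
            cols[term] = df["group"].to_numpy(dtype=float)
        elif term == "plz_mean:group":
            cols[term] = cols["plz_mean"] * cols["group"]
        elif term == "plz_cv:group":
            cols[term] = cols["plz_cv"] * cols["group"]
    X = np.column_stack([cols[t] for t in spec.terms])

    for j, term in enumerate(spec.terms):
        if term != "intercept" and np.ptp(X[:, j]) == 0:
            raise EstimationError(f"degenerate predictor column: {term}")

    codes, _ = pd.factorize(df["participant_id"])
    return y, X, codes.astype(np.int64), tuple(spec.terms)


# ---------------------------------------------------------------------------
# marginal likelihood


def _group_logpost(y, eta0, g, J, sigma2, u):
    eta = eta0 + u[g]
    ll = y * eta - np.logaddexp(0.0, eta)
    return np.bincount(g, weights=ll, minlength=J) - u**2 / (2 * sigma2)


def _posterior_modes(y, eta0, g, J, sigma2, tol=1e-11, max_iter=200):
    """Per-group damped Newton solve for the random-intercept posterior mode.

    The log posterior in u is strictly concave, but a full Newton step can
    overshoot badly when the likelihood is saturated (mu near 0/1 leaves only
    the prior curvature), so each group's step is halved until its log
    posterior does not decrease.
    """
    u = np.zeros(J)
    f = _group_logpost(y, eta0, g, J, sigma2, u)
    for _ in range(max_iter):
        eta = eta0 + u[g]
        mu = special.expit(eta)
        grad = np.bincount(g, weights=y - mu, minlength=J) - u / sigma2
        prec = np.bincount(g, weights=mu * (1 - mu), minlength=J) + 1.0 / sigma2
        step = grad / prec
        t = np.ones(J)
        for _ in range(40):
            f_new = _group_logpost(y, eta0, g, J, sigma2, u + t * step)
            overshoot = f_new < f - 1e-12
            if not overshoot.any():
                break
            t[overshoot] *= 0.5
        u = u + t * step
        f = f_new
        if np.max(np.abs(t * step)) < tol:
            break
    eta = eta0 + u[g]
    mu = special.expit(eta)
    prec = np.bincount(g, weights=mu * (1 - mu), minlength=J) + 1.0 / sigma2
    return u, prec


def marginal_loglik(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    gamma: np.ndarray,
    sigma_u: float,
    n_nodes: int = 25,
) -> float:
    """Marginal log-likelihood of a random-intercept logistic model.

    Sums, over participants, the log of the Bernoulli likelihood integrated
    against the N(0, sigma_u^2) intercept density; each integral uses the
    adaptive Gauss-Hermite rule with ``n_nodes`` nodes.  ``sigma_u = 0`` is
    evaluated exactly as the ordinary logistic log-likelihood.
    """
    y = np.asarray(y, dtype=float)
    eta0 = X @ gamma
    if not np.all(np.isfinite(eta0)):
        bad = int(np.flatnonzero(~np.isfinite(eta0))[0])
        raise FloatingPointError(f"non-finite linear predictor at row {bad}")
    if sigma_u == 0:
        return float(np.sum(y * eta0 - np.logaddexp(0.0, eta0)))

    J = int(groups.max()) + 1
    sigma2 = sigma_u**2
    u_hat, prec = _posterior_modes(y, eta0, groups, J, sigma2)
    tau = 1.0 / np.sqrt(prec)

    z, w = hermgauss(n_nodes)
    # K x J node positions
    un = u_hat[None, :] + math.sqrt(2.0) * tau[None, :] * z[:, None]

    # group sums vectorised across nodes: sort rows by group once, reduceat
    order = np.argsort(groups, kind="stable")
    g_sorted = groups[order]
    starts = np.searchsorted(g_sorted, np.arange(J))
    eta = eta0[order][None, :] + un[:, g_sorted]
    ll = y[order][None, :] * eta - np.logaddexp(0.0, eta)
    h = np.add.reduceat(ll, starts, axis=1)

    const = -0.5 * math.log(2 * math.pi * sigma2)
    h += const - un**2 / (2 * sigma2)
    log_terms = (np.log(w) + z**2)[:, None] + h
    ll_j = 0.5 * math.log(2.0) + np.log(tau) + special.logsumexp(log_terms, axis=0)
    return float(ll_j.sum())


def _logistic_start(y, X, ridge=1e-8, max_iter=50):
    """Plain logistic IRLS used only for starting values."""
    p = X.shape[1]
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        W = mu * (1 - mu) + 1e-10
        H = X.T @ (X * W[:, None]) + ridge * np.eye(p)
        grad = X.T @ (y - mu) - ridge * beta
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    beta = np.clip(beta, -15, 15)  # quasi-separated starts destabilise BFGS
    return beta


def _numeric_hessian(f, theta, rel_step=1e-4):
    """Central-difference Hessian of a scalar function."""
    p = len(theta)
    h = rel_step * np.maximum(1.0, np.abs(theta))
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(theta + ei + ej)
            fpm = f(theta + ei - ej)
            fmp = f(theta - ei + ej)
            fmm = f(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def fit(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Maximum-likelihood fit of one model of the family.

    Deterministic given (spec, data): starting values are the ordinary
    logistic fit for the fixed effects with sigma_u initialised at 1; the
    variance is optimised on the log-SD scale.  Standard errors come from the
    inverse observed information at the optimum.
    """
    y, X, groups, terms = build_design(data, spec)
    n_obs = len(y)
    n_groups = int(groups.max()) + 1
    p = X.shape[1]
    nodes = spec.quadrature_nodes

    # optimise on internally standardised predictors: the raw-scale design is
    # often badly conditioned (uncentred metrics in the hundreds), which hurts
    # both BFGS and the finite-difference information matrix.  The linear map
    # A sends standardised coefficients back to the raw scale exactly.
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    mean[0], scale[0] = 0.0, 1.0  # intercept untouched
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    A = np.zeros((p + 1, p + 1))
    A[0, 0] = 1.0
    for j in range(1, p):
        A[j, j] = 1.0 / scale[j]
        A[0, j] = -mean[j] / scale[j]
    A[p, p] = 1.0  # log sigma_u passes through

    def negll(theta):
        gamma = theta[:p]
        sigma = math.exp(min(max(theta[p], -8.0), 5.0))
        try:
            return -marginal_loglik(y, Z, groups, gamma, sigma, nodes)
        except FloatingPointError:
            return np.inf

    gamma0 = _logistic_start(y, Z)
    theta0 = np.concatenate([gamma0, [0.0]])  # log sigma_u = 0 -> sigma_u = 1

    # BFGS with central-difference gradients; restarting with a fresh Hessian
    # approximation escapes the occasional precision-loss stall
    best = None
    theta = theta0
    converged = False
    for _ in range(4):
        res = optimize.minimize(
            negll, theta, method="BFGS", jac="3-point",
            options={"maxiter": spec.max_iter, "gtol": 1e-8},
        )
        improved = best is None or res.fun < best.fun - 1e-9
        if best is None or res.fun < best.fun:
            best = res
        theta = best.x
        converged = converged or bool(res.success)
        if not improved:
            break
    # derivative-free polish from the best BFGS point
    res2 = optimize.minimize(
        negll, theta, method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 3000},
    )
    if res2.fun < best.fun:
        theta = res2.x
        converged = converged or bool(res2.success)

    loglik = -negll(theta)
    gamma = (A @ theta)[:p]
    sigma_u = math.exp(theta[p])

    H = _numeric_hessian(negll, theta)
    try:
        cov_std = np.linalg.inv(H)
        if np.any(np.diag(cov_std)[:p] <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("observed information not positive definite; "
                      "using pseudo-inverse for standard errors")
        cov_std = np.linalg.pinv(H)
    cov = A @ cov_std @ A.T

    se = np.sqrt(np.abs(np.diag(cov)[:p]))
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = gamma / se
    pvals = 2 * stats.norm.sf(np.abs(zvals))

    sigma_u2 = sigma_u**2
    fitobj = ModelFit(
        spec=spec,
        terms=terms,
        coefficients={t: float(b) for t, b in zip(terms, gamma)},
        se={t: float(s) for t, s in zip(terms, se)},
        p={t: float(v) for t, v in zip(terms, pvals)},
        odds_ratios={t: float(np.exp(b)) for t, b in zip(terms, gamma)},
        sigma_u2=float(sigma_u2),
        icc=float(sigma_u2 / (sigma_u2 + LATENT_RESIDUAL_VAR)),
        loglik=float(loglik),
        converged=converged,
        n_obs=n_obs,
        n_groups=n_groups,
        quasi_separated=bool(np.any(np.abs(gamma) > 15)),
        cov=cov,
    )
    return fitobj


def icc(fitted: ModelFit) -> float:
    """Intraclass correlation from the intercept-only (null) model.

    Latent-threshold convention for a dichotomous outcome:
    ``sigma_u^2 / (sigma_u^2 + pi^2/3)``.  The complement is the
    within-person variance share.
    """
    if fitted.spec.name != "null":
        raise UsageError("ICC is defined on the null (intercept-only) fit")
    return fitted.sigma_u2 / (fitted.sigma_u2 + LATENT_RESIDUAL_VAR)


def lrt(full: ModelFit, reduced: pd.DataFrame | ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested pair (secondary to Wald reporting)."""
    stat = 2 * (full.loglik - reduced.loglik)
    df = len(full.terms) - len(reduced.terms)
    return stat, df, float(stats.chi2.sf(max(stat, 0.0), max(df, 1)))


def run_model_family(
    data: pd.DataFrame,
    quadrature_nodes: int = 25,
) -> dict[tuple[str, str, str], ModelFit]:
    """Fit the full battery: models 1-2 for each metric x configuration
    (8 fits) plus model 3 on the OA subset (4 fits)."""
    fits: dict[tuple[str, str, str], ModelFit] = {}
    for cfg in ("long", "trans"):
        for metric in ("r128", "x40"):
            for name in ("model1", "model2", "model3"):
                spec = ModelSpec(
                    name=name,
                    metric=metric,
                    configuration=cfg,
                    quadrature_nodes=quadrature_nodes,
                )
                fits[(name, metric, cfg)] = fit(spec, data)
    return fits


def family_table(fits: dict[tuple[str, str, str], ModelFit]) -> pd.DataFrame:
    """Flatten a battery of fits into one grid (model, metric, config, term)."""
    rows = []
    for (name, metric, cfg), f in fits.items():
        frame = f.to_frame()
        frame.insert(0, "model", name)
        frame.insert(1, "metric", metric)
        frame.insert(2, "config", cfg)
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)
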