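"""Random-intercept logistic regression for patients clustered in practices.

Model: y_ij ~ Bernoulli(p_ij), logit(p_ij) = x_ij' beta + u_j, with
practice effects u_j ~ N(0, sigma_u^2). The marginal likelihood
integrates each cluster's Bernoulli-logit contribution over the Gaussian
random intercept; the integral is approximated by adaptive Gauss-Hermite
quadrature (nodes centred and scaled at each cluster's posterior mode,
15 nodes by default). The intraclass correlation on the latent
(threshold) scale is sigma_u^2 / (sigma_u^2 + pi^2/3), the conventional
ICC for multilevel logistic models, where pi^2/3 is the variance of the
standard logistic residual.

The estimator follows scikit-learn conventions (``fit``,
``get_params``/``set_params``, trailing-underscore fitted attributes);
:func:`fit_random_intercept_logit` wraps it with the categorical
covariate coding (reference levels, ordered dummies) used by the
analysis tables.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "RandomInterceptLogit",
    "Covariate",
    "GlmmSpec",
    "GlmmFit",
    "icc_from_sigma",
    "sigma_from_icc",
    "build_design",
    "fit_random_intercept_logit",
    "odds_ratios",
    "ConvergenceError",
]

logger = logging.getLogger(__name__)

_LOGISTIC_VAR = math.pi**2 / 3.0
_SIGMA_FLOOR = 1e-8  # below this the model is treated as an ordinary GLM


class ConvergenceError(RuntimeError):
    pass


def icc_from_sigma(sigma_u: float) -> float:
    """Latent-scale ICC: sigma_u^2 / (sigma_u^2 + pi^2/3)."""
    if sigma_u < 0:
        raise ValueError("sigma_u must be non-negative")
    return sigma_u**2 / (sigma_u**2 + _LOGISTIC_VAR)


def sigma_from_icc(icc: float) -> float:
    """Inverse of :func:`icc_from_sigma` (icc in [0, 1))."""
    if not 0 <= icc < 1:
        raise ValueError("icc must lie in [0, 1)")
    return math.sqrt(icc * _LOGISTIC_VAR / (1 - icc))


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # y*eta - log(1 + exp(eta)), stable for large |eta|
    return y * eta - np.logaddexp(0.0, eta)


class RandomInterceptLogit:
    """Maximum-likelihood random-intercept logistic regression.

    Parameters
    ----------
    n_quadrature : int
        Number of adaptive Gauss-Hermite nodes per cluster integral.
    fit_intercept : bool
        Prepend a constant column to the design.
    max_iter : int
        L-BFGS-B iteration cap for the marginal-likelihood optimisation.
    tol : float
        Convergence check: max-norm of the central-difference gradient of
        the mean (per-observation) negative log-likelihood must be below
        this for ``converged_`` to be True.

    Fitted attributes
    -----------------
    ``params_`` (intercept first if fitted), ``bse_``, ``sigma_u_``,
    ``sigma_u_se_``, ``icc_``, ``loglik_``, ``converged_``, ``n_iter_``,
    ``loglik_path_`` (objective at accepted optimiser steps),
    ``ranef_mode_`` (posterior modes per cluster).
    """

    def __init__(self, n_quadrature: int = 15, fit_intercept: bool = True,
                 max_iter: int = 200, tol: float = 1e-5,
                 sigma_fixed: float | None = None):
        self.n_quadrature = n_quadrature
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter
        self.tol = tol
        # constrain the random-intercept SD (e.g. 0 for an ordinary
        # logistic fit through the same code path, or for LR tests of it)
        self.sigma_fixed = sigma_fixed

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_quadrature": self.n_quadrature,
            "fit_intercept": self.fit_intercept,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "sigma_fixed": self.sigma_fixed,
        }

    def set_params(self, **params) -> "RandomInterceptLogit":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- numerical core ----------------------------------------------------
    def _prepare(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("outcome must have both levels present")
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        codes, uniques = pd.factorize(np.asarray(groups))
        if len(uniques) < 2:
            raise ValueError("need at least 2 clusters")
        return X, y, codes, len(uniques)

    @staticmethod
    def _posterior_modes(eta0, y, gidx, n_g, sigma, max_newton=100):
        """Per-cluster modes of log p(y_j | u) + log phi(u; sigma), by
        damped Newton on the scalar concave objective (vectorised over
        clusters). Returns (mode u, negative curvature at mode)."""
        u = np.zeros(n_g)
        inv_s2 = 1.0 / sigma**2
        for _ in range(max_newton):
            p = expit(eta0 + u[gidx])
            grad = np.bincount(gidx, weights=y - p, minlength=n_g) - u * inv_s2
            curv = np.bincount(gidx, weights=p * (1 - p), minlength=n_g) + inv_s2
            step = grad / curv
            np.clip(step, -4.0, 4.0, out=step)
            u += step
            if np.max(np.abs(step)) < 1e-10:
                break
        p = expit(eta0 + u[gidx])
        curv = np.bincount(gidx, weights=p * (1 - p), minlength=n_g) + inv_s2
        return u, curv

    def _marginal_loglik(self, params, X, y, gidx, n_g, nodes, logw):
        """Total marginal log-likelihood at (beta, sigma)."""
        beta, sigma = params[:-1], params[-1]
        eta0 = X @ beta
        if sigma < _SIGMA_FLOOR:
            return float(np.sum(_bernoulli_loglik(eta0, y)))
        u_hat, curv = self._posterior_modes(eta0, y, gidx, n_g, sigma)
        tau = 1.0 / np.sqrt(curv)  # adaptive scale per cluster
        # integrand at transformed nodes u = u_hat + sqrt(2) tau z_k
        log_terms = np.empty((len(nodes), n_g))
        log_prior_const = -0.5 * math.log(2 * math.pi) - math.log(sigma)
        for k, (z, lw) in enumerate(zip(nodes, logw)):
            u_k = u_hat + math.sqrt(2.0) * tau * z
            ll_data = np.bincount(
                gidx, weights=_bernoulli_loglik(eta0 + u_k[gidx], y), minlength=n_g
            )
            log_prior = log_prior_const - u_k**2 / (2 * sigma**2)
            log_terms[k] = lw + z**2 + ll_data + log_prior
        m = log_terms.max(axis=0)
        integral = m + np.log(np.sum(np.exp(log_terms - m), axis=0))
        return float(np.sum(integral + 0.5 * math.log(2.0) + np.log(tau)))

    @staticmethod
    def _irls_init(X, y, ridge=1e-6, n_iter=25):
        """Plain Newton/IRLS logistic fit used only for initialisation."""
        beta = np.zeros(X.shape[1])
        for _ in range(n_iter):
            p = expit(X @ beta)
            W = p * (1 - p) + 1e-10
            H = (X * W[:, None]).T @ X + ridge * np.eye(X.shape[1])
            g = X.T @ (y - p) - ridge * beta
            step = np.linalg.solve(H, g)
            beta += step
            if np.max(np.abs(step)) < 1e-10:
                break
        return beta

    @staticmethod
    def _check_separation(X, y, offset):
        """Warn on binary design columns whose active rows have constant
        outcome (quasi-separation); return {col_idx: +/-inf}."""
        flagged = {}
        for j in range(offset, X.shape[1]):
            col = X[:, j]
            vals = np.unique(col)
            if not set(vals).issubset({0.0, 1.0}):
                continue
            on = y[col == 1.0]
            if len(on) and (on.min() == on.max()):
                sign = math.inf if on[0] == 1.0 else -math.inf
                warnings.warn(
                    f"possible separation: design column {j} has constant "
                    f"outcome {int(on[0])} among its {len(on)} active rows; "
                    "its estimate is flagged non-finite",
                    RuntimeWarning, stacklevel=3,
                )
                flagged[j] = sign
        return flagged

    def fit(self, X, y, groups) -> "RandomInterceptLogit":
        Xd, yv, gidx, n_g = self._prepare(X, y, groups)
        n, p = Xd.shape
        nodes, w = np.polynomial.hermite.hermgauss(self.n_quadrature)
        logw = np.log(w)
        sep = self._check_separation(Xd, yv, 1 if self.fit_intercept else 0)

        def nll_mean(params):
            return -self._marginal_loglik(params, Xd, yv, gidx, n_g, nodes, logw) / n

        beta0 = self._irls_init(Xd, yv)
        if self.sigma_fixed is not None:
            if self.sigma_fixed < 0:
                raise ValueError("sigma_fixed must be non-negative")
            x0 = np.append(beta0, self.sigma_fixed)
            bounds = [(None, None)] * p + [(self.sigma_fixed, self.sigma_fixed)]
        else:
            x0 = np.append(beta0, 0.3)
            bounds = [(None, None)] * p + [(0.0, None)]
        path: list[float] = []

        def cb(xk):
            path.append(-nll_mean(xk) * n)

        res = minimize(
            nll_mean, x0, method="L-BFGS-B", bounds=bounds, callback=cb,
            options={"maxiter": self.max_iter, "ftol": 1e-13, "gtol": 1e-8},
        )
        theta = res.x
        grad = self._fd_gradient(nll_mean, theta)
        # a variance component this small is indistinguishable from the
        # boundary; report it as exactly 0 (ordinary logistic regression)
        at_boundary = theta[-1] < 1e-4
        g_check = np.abs(grad.copy())
        if self.sigma_fixed is not None:
            g_check[-1] = 0.0  # sigma axis constrained, not optimised
        elif at_boundary and grad[-1] > 0:
            g_check[-1] = 0.0  # pushing sigma below 0 is not a failure
        converged = bool(res.success) and float(np.max(g_check)) < self.tol
        if not converged:
            logger.warning(
                "GLMM optimiser did not meet the convergence criterion "
                "(status=%s, max|grad|=%.2e)", res.message, float(np.max(g_check)),
            )

        H = self._fd_hessian(lambda t: nll_mean(t) * n, theta,
                             skip_last=at_boundary or self.sigma_fixed is not None)
        bse = self._se_from_hessian(H)

        self.n_features_in_ = p - (1 if self.fit_intercept else 0)
        self.params_ = theta[:-1].copy()
        self.bse_ = bse[:-1].copy()
        for j, sign in sep.items():
            self.params_[j] = sign
            self.bse_[j] = math.inf
        if self.fit_intercept:
            self.intercept_ = self.params_[0]
            self.coef_ = self.params_[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = self.params_
        if self.sigma_fixed is not None:
            self.sigma_u_ = float(self.sigma_fixed)
        else:
            self.sigma_u_ = float(theta[-1]) if not at_boundary else 0.0
        self.sigma_u_se_ = float(bse[-1])
        self.icc_ = icc_from_sigma(self.sigma_u_)
        self.loglik_ = -nll_mean(theta) * n
        self.converged_ = converged
        self.n_iter_ = int(res.nit)
        self.loglik_path_ = path
        self.n_obs_ = n
        self.n_clusters_ = n_g
        if self.sigma_u_ > 0:
            eta0 = Xd @ theta[:-1]
            self.ranef_mode_, _ = self._posterior_modes(
                eta0, yv, gidx, n_g, self.sigma_u_
            )
        else:
            self.ranef_mode_ = np.zeros(n_g)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Population-averaged probabilities at u = 0 (two-column)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        p = expit(self.intercept_ + X @ self.coef_)
        return np.column_stack([1 - p, p])

    # -- derivatives by central differences -------------------------------
    @staticmethod
    def _fd_gradient(f, x, h=1e-6):
        g = np.zeros_like(x)
        for i in range(len(x)):
            hi = h * max(1.0, abs(x[i]))
            xp, xm = x.copy(), x.copy()
            xp[i] += hi
            xm[i] = max(xm[i] - hi, 0.0) if i == len(x) - 1 else xm[i] - hi
            g[i] = (f(xp) - f(xm)) / (xp[i] - xm[i])
        return g

    @staticmethod
    def _fd_hessian(f, x, h=1e-4, skip_last=False):
        k = len(x) - (1 if skip_last else 0)
        H = np.full((len(x), len(x)), np.nan)
        hs = [h * max(1.0, abs(xi)) for xi in x]

        def shifted(i, si, j, sj):
            xx = x.copy()
            xx[i] += si * hs[i]
            xx[j] += sj * hs[j]
            if xx[-1] < 0:
                xx[-1] = 0.0
            return f(xx)

        for i in range(k):
            for j in range(i, k):
                H[i, j] = H[j, i] = (
                    shifted(i, 1, j, 1) - shifted(i, 1, j, -1)
                    - shifted(i, -1, j, 1) + shifted(i, -1, j, -1)
                ) / (4 * hs[i] * hs[j])
        return H

    @staticmethod
    def _se_from_hessian(H):
        se = np.full(H.shape[0], np.nan)
        k = H.shape[0] - (1 if np.isnan(H[-1, -1]) else 0)
        block = H[:k, :k]
        try:
            cov = np.linalg.inv(block)
            d = np.diag(cov)
            with np.errstate(invalid="ignore"):
                se[:k] = np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            logger.warning("observed information not invertible; SEs unavailable")
        return se


# -- covariate coding and labelled fits -----------------------------------

@dataclass(frozen=True)
class Covariate:
    """A categorical fixed effect with an explicit reference level."""

    name: str
    levels: tuple[str, ...]
    ref: str

    def __post_init__(self):
        if self.ref not in self.levels:
            raise ValueError(f"{self.name}: reference {self.ref!r} not in levels")


@dataclass
class GlmmSpec:
    """Outcome, covariates (ordered, with reference levels), and cluster."""

    outcome: str
    covariates: list[Covariate]
    cluster: str = "practice_id"


@dataclass
class GlmmFit:
    """Labelled results of one random-intercept logistic fit."""

    spec: GlmmSpec
    terms: list[str]  # dummy-column labels, matching beta[1:]
    beta: np.ndarray  # intercept first
    se: np.ndarray
    sigma_u: float
    sigma_u_se: float
    icc: float
    loglik: float
    converged: bool
    n_quadrature: int
    n_obs: int
    n_clusters: int
    model: RandomInterceptLogit = field(repr=False, default=None)


def build_design(data: pd.DataFrame, spec: GlmmSpec) -> tuple[pd.DataFrame, list[str]]:
    """Dummy-code the spec's categorical covariates against their
    reference levels, preserving level order."""
    cols = {}
    labels = []
    for cov in spec.covariates:
        observed = set(data[cov.name].astype(str))
        unknown = observed - set(cov.levels)
        if unknown:
            raise ValueError(f"{cov.name}: unknown level(s) {sorted(unknown)}")
        for lev in cov.levels:
            if lev == cov.ref:
                continue
            lab = f"{cov.name}[{lev}]"
            cols[lab] = (data[cov.name].astype(str) == lev).astype(float)
            labels.append(lab)
    X = pd.DataFrame(cols, index=data.index) if cols else pd.DataFrame(index=data.index)
    return X, labels


def fit_random_intercept_logit(
    data: pd.DataFrame,
    spec: GlmmSpec,
    n_quadrature: int = 15,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> GlmmFit:
    """Fit the spec'd model on a patient table.

    ``data`` must contain the outcome column (0/1 or bool), every
    covariate column, and the cluster column. An empty covariate list
    fits the empty (intercept + random intercept) model used for ICC
    estimation.
    """
    y = data[spec.outcome].astype(int).to_numpy()
    X, labels = build_design(data, spec)
    model = RandomInterceptLogit(
        n_quadrature=n_quadrature, fit_intercept=True, max_iter=max_iter, tol=tol
    )
    model.fit(X.to_numpy() if labels else np.empty((len(data), 0)), y,
              data[spec.cluster].to_numpy())
    beta = np.append(model.intercept_, model.coef_)
    se = model.bse_.copy()
    return GlmmFit(
        spec=spec, terms=labels, beta=beta, se=se,
        sigma_u=model.sigma_u_, sigma_u_se=model.sigma_u_se_,
        icc=model.icc_, loglik=model.loglik_, converged=model.converged_,
        n_quadrature=n_quadrature, n_obs=model.n_obs_, n_clusters=model.n_clusters_,
        model=model,
    )


def odds_ratios(fit: GlmmFit, ci_level: float = 0.95) -> pd.DataFrame:
    """Odds ratios with Wald CIs per covariate level.

    Reference levels appear with ``reference = True`` and OR 1. Refuses
    non-converged fits (their Wald intervals would be meaningless).
    """
    from scipy.stats import norm

    if not fit.converged:
        raise ConvergenceError(
            "fit did not converge; refusing to report odds ratios"
        )
    z = norm.ppf(0.5 + ci_level / 2)
    idx = {lab: i for i, lab in enumerate(fit.terms)}
    rows = []
    for cov in fit.spec.covariates:
        for lev in cov.levels:
            if lev == cov.ref:
                rows.append((cov.name, lev, True, 0.0, 0.0, 1.0, 1.0, 1.0))
                continue
            i = idx[f"{cov.name}[{lev}]"]
            b, s = fit.beta[i + 1], fit.se[i + 1]
            rows.append((
                cov.name, lev, False, b, s,
                math.exp(b) if np.isfinite(b) else b,
                math.exp(b - z * s) if np.isfinite(b) and np.isfinite(s) else np.nan,
                math.exp(b + z * s) if np.isfinite(b) and np.isfinite(s) else np.nan,
            ))
    return pd.DataFrame(
        rows, columns=["term", "level", "reference", "beta", "se", "or_", "ci_lo", "ci_hi"]
    )
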