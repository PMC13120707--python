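"""Global (non-spatial) baseline models: OLS, Poisson, and NB2.

The count models use the log link ln(mu) = ln(t) + X beta.  The negative
binomial is NB2 — Var(y) = mu + alpha mu^2 — fitted by profile likelihood:
for fixed alpha the beta coefficients come from an IRLS (GLM) fit, and the
profiled log-likelihood is maximized over ln(alpha) on [1e-8, 1e4] by
bounded scalar search.  When the data are equidispersed the alpha estimate
lands on the lower boundary and the fit reduces to Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy import stats

from .types import GWCrashError, SpatialUnitTable

ALPHA_MIN = 1e-8
ALPHA_MAX = 1e4


def nb2_loglik(y: np.ndarray, mu: np.ndarray, alpha) -> float:
    """NB2 log-likelihood, elementwise terms summed (log-gamma form)."""
    return float(np.sum(nb2_loglik_terms(y, mu, alpha)))


def nb2_loglik_terms(y: np.ndarray, mu: np.ndarray, alpha) -> np.ndarray:
    """Per-observation NB2 log-density at mean mu and dispersion alpha.

    Written via log-gamma so the Gamma functions are never evaluated
    directly:  y ln(alpha mu) - (y + 1/alpha) ln(1 + alpha mu)
    + lnG(y + 1/alpha) - lnG(1/alpha) - lnG(y + 1).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    a = np.asarray(alpha, dtype=float)
    if np.any(a <= 0):
        raise GWCrashError("alpha must be positive")
    if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
        bad = int(np.argmin(np.where(np.isfinite(mu), mu, -np.inf)))
        raise GWCrashError(f"non-positive or non-finite mean at position {bad}")
    inv_a = 1.0 / a
    return (
        y * np.log(a * mu)
        - (y + inv_a) * np.log1p(a * mu)
        + gammaln(y + inv_a)
        - gammaln(inv_a)
        - gammaln(y + 1.0)
    )


@dataclass
class GlobalFit:
    """A fitted global model with enough state for diagnostics."""

    family: str  # ols | poisson | negbin
    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    log_likelihood: float
    fitted_mu: np.ndarray
    k: int  # parameter count entering AIC
    y: np.ndarray
    X: np.ndarray
    alpha: Optional[float] = None
    alpha_se: Optional[float] = None
    converged: bool = True
    n_iterations: int = 0
    boundary_alpha: bool = False
    log_offset: Optional[np.ndarray] = None
    extra: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.k

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.zvalues))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.params,
                "SE": self.bse,
                "statistic": self.zvalues,
                "p": self.pvalues,
            }
        )

    def residuals(self, kind: str = "deviance") -> np.ndarray:
        """Deviance or Pearson residuals appropriate to the family."""
        y, mu = self.y, self.fitted_mu
        if self.family == "ols":
            return y - mu
        if kind == "pearson":
            var = mu if self.family == "poisson" else mu + self.alpha * mu**2
            return (y - mu) / np.sqrt(var)
        if self.family == "poisson":
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(y > 0, y * np.log(y / mu), 0.0)
            d = 2 * (term - (y - mu))
        else:
            a = self.alpha
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(y > 0, y * np.log(y / mu), 0.0)
            d = 2 * (term - (y + 1 / a) * np.log((1 + a * y) / (1 + a * mu)))
        return np.sign(y - mu) * np.sqrt(np.maximum(d, 0.0))


def _design(units: SpatialUnitTable, covariates: Optional[Sequence[str]]):
    covs = list(covariates) if covariates is not None else list(units.covariates)
    X = units.design_matrix(covs)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise GWCrashError("design matrix is rank deficient")
    terms = ["Intercept"] + covs
    return X, terms


def _check_counts(y: np.ndarray) -> np.ndarray:
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise GWCrashError("count response must be nonnegative integers")
    return np.asarray(y, dtype=float)


def fit_ols(
    units: SpatialUnitTable, covariates: Optional[Sequence[str]] = None
) -> GlobalFit:
    """Least squares with a Gaussian ML log-likelihood (for AIC comparability)."""
    X, terms = _design(units, covariates)
    y = units.response_vector()
    res = sm.OLS(y, X).fit()
    # Gaussian ML loglik: -n/2 (ln(2 pi sigma2_hat) + 1), sigma2_hat = RSS/n
    return GlobalFit(
        family="ols",
        terms=terms,
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        log_likelihood=float(res.llf),
        fitted_mu=np.asarray(res.fittedvalues),
        k=X.shape[1] + 1,  # + sigma^2
        y=y,
        X=X,
        extra={"r_squared": float(res.rsquared)},
    )


def fit_poisson(
    units: SpatialUnitTable,
    covariates: Optional[Sequence[str]] = None,
    offset: bool = True,
) -> GlobalFit:
    """Poisson GLM with log link and optional ln(t) offset."""
    X, terms = _design(units, covariates)
    y = _check_counts(units.response_vector())
    log_t = units.log_offset() if offset else np.zeros(units.n)
    res = sm.GLM(y, X, family=sm.families.Poisson(), offset=log_t).fit(
        tol=1e-10, maxiter=200
    )
    if not res.converged:
        raise GWCrashError(f"Poisson IRLS failed to converge in {res.fit_history['iteration']} iterations")
    return GlobalFit(
        family="poisson",
        terms=terms,
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        log_likelihood=float(res.llf),
        fitted_mu=np.asarray(res.mu),
        k=X.shape[1],
        y=y,
        X=X,
        converged=bool(res.converged),
        n_iterations=int(res.fit_history["iteration"]),
        log_offset=log_t,
    )


def _nb_beta_given_alpha(y, X, log_t, alpha, start=None):
    fam = sm.families.NegativeBinomial(alpha=alpha)
    res = sm.GLM(y, X, family=fam, offset=log_t).fit(
        tol=1e-10, maxiter=200, start_params=start
    )
    return res


def fit_negbin(
    units: SpatialUnitTable,
    covariates: Optional[Sequence[str]] = None,
    offset: bool = True,
) -> GlobalFit:
    """NB2 fit by profile likelihood over alpha.

    alpha is estimated by safeguarded bounded maximization of the profile
    log-likelihood on [1e-8, 1e4] (search over ln alpha); at each probe
    beta is re-fit by IRLS.  Equidispersed data drive alpha to the lower
    bound, which is reported with a boundary flag.
    """
    X, terms = _design(units, covariates)
    y = _check_counts(units.response_vector())
    log_t = units.log_offset() if offset else np.zeros(units.n)

    start = {"params": None}

    def negprof(log_a: float) -> float:
        a = float(np.exp(log_a))
        res = _nb_beta_given_alpha(y, X, log_t, a, start["params"])
        start["params"] = np.asarray(res.params)
        return -nb2_loglik(y, np.asarray(res.mu), a)

    opt = minimize_scalar(
        negprof,
        bounds=(np.log(ALPHA_MIN), np.log(ALPHA_MAX)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    alpha_hat = float(np.exp(opt.x))
    # Brent cannot land exactly on the bound; declare a boundary solution
    # when the profile at alpha_min is at least as good as the interior one
    boundary = negprof(np.log(ALPHA_MIN)) <= float(opt.fun) + 1e-6
    if boundary:
        alpha_hat = ALPHA_MIN
    res = _nb_beta_given_alpha(y, X, log_t, alpha_hat)
    mu = np.asarray(res.mu)
    ll = nb2_loglik(y, mu, alpha_hat)

    # alpha SE from the numerical curvature of the profile loglik in alpha
    alpha_se = None
    if not boundary:
        h = max(1e-5, 1e-4 * alpha_hat)
        la = np.log(alpha_hat)
        d2 = (negprof(la + h) - 2 * (-ll) + negprof(la - h)) / h**2
        if d2 > 0:  # curvature of -loglik in log alpha; delta method to alpha
            alpha_se = alpha_hat / np.sqrt(d2)

    return GlobalFit(
        family="negbin",
        terms=terms,
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        log_likelihood=ll,
        fitted_mu=mu,
        k=X.shape[1] + 1,  # + alpha
        y=y,
        X=X,
        alpha=alpha_hat,
        alpha_se=alpha_se,
        converged=bool(res.converged) and bool(opt.success),
        n_iterations=int(opt.nfev),
        boundary_alpha=boundary,
        log_offset=log_t,
    )


def dispersion_statistic(fit: GlobalFit) -> float:
    """Pearson chi-square over residual degrees of freedom (n - k).

    Values near 1 indicate a correctly specified variance; values well
    above 1 flag overdispersion relative to the fitted family.
    """
    if fit.family not in ("poisson", "negbin"):
        raise GWCrashError("dispersion statistic is defined for count families")
    n, k = fit.n, len(fit.params)
    if n <= k:
        raise GWCrashError("no residual degrees of freedom")
    mu = fit.fitted_mu
    var = mu if fit.family == "poisson" else mu + fit.alpha * mu**2
    chi2 = float(np.sum((fit.y - mu) ** 2 / var))
    return chi2 / (n - k)
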