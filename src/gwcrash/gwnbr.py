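"""Geographically weighted negative binomial regression.

The model lets both the regression coefficients and the NB2 dispersion
vary over space:

    y_j ~ NB( t_j * exp(sum_k beta_k(u_j, v_j) x_jk), alpha(u_j, v_j) )

Estimation is by locally weighted maximum likelihood.  At each focal unit
i a kernel assigns distance-decay weights w(d_ij) to every unit, and the
local weighted NB2 log-likelihood

    L_i(beta, alpha) = sum_j w(d_ij) * lnNB2(y_j; mu_j(beta), alpha)

is maximized by alternating (a) IRLS steps for beta,

    beta <- [X' W A X]^-1 X' W A z,
    A = diag( mu_j / (1 + alpha mu_j) ),       (GLM working weights)
    z_j = x_j' beta + (y_j - mu_j) / mu_j,     (adjusted response)

with step-halving to keep the weighted likelihood non-decreasing, and
(b) one-dimensional bounded maximization over ln(alpha).  Note that the
adjusted-response increment (y - mu)/mu equals (y - mu) / [a_j (1 +
alpha mu_j)] with a_j the IRLS working weight — the two common ways of
writing the NB working response are the same quantity.

Model complexity for AIC uses the trace of the hat-like matrix S whose
i-th row is x_i' [X' W_i A_i X]^-1 X' W_i A_i, the standard effective
number of parameters of a locally weighted regression.  The bandwidth is
chosen by golden-section search of either the AIC or a leave-one-out CV
score over the admissible bandwidth range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy import stats

from .glm import ALPHA_MAX, ALPHA_MIN, fit_negbin, nb2_loglik_terms
from .types import GWCrashError, SpatialUnitTable
from .weights import KernelSpec, kernel_weight_vector


@dataclass
class LocalFitState:
    """Inputs of one focal-unit fit (active set = units with positive weight)."""

    focal: int
    y: np.ndarray
    X: np.ndarray
    log_t: np.ndarray
    w: np.ndarray  # kernel weights, same length as y

    def __post_init__(self) -> None:
        if np.any(self.w < 0) or np.any(self.w > 1 + 1e-12):
            raise GWCrashError("kernel weights must lie in [0, 1]")


@dataclass
class LocalFitResult:
    beta: np.ndarray
    alpha: float
    cov: np.ndarray
    loglik: float  # weighted local loglik at the optimum
    converged: bool
    n_iterations: int
    ll_trace: list[float] = field(default_factory=list)  # per outer iteration


@dataclass
class GWNBRFit:
    units_index: pd.Index
    terms: list[str]
    local_beta: np.ndarray  # n x p
    local_alpha: np.ndarray  # n
    local_se: np.ndarray  # n x p
    fitted_mu: np.ndarray  # n
    kernel: KernelSpec
    effective_params: float
    global_loglik: float
    y: np.ndarray
    X: np.ndarray
    log_offset: np.ndarray
    global_alpha: bool = False
    cv_score: Optional[float] = None
    per_unit_convergence: np.ndarray = field(default_factory=lambda: np.array([], bool))

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def local_tstat(self) -> np.ndarray:
        return self.local_beta / self.local_se

    @property
    def aic(self) -> float:
        return -2.0 * self.global_loglik + 2.0 * self.effective_params

    def residuals(self, kind: str = "deviance") -> np.ndarray:
        """Per-unit residuals of the locally fitted means."""
        y, mu, a = self.y, self.fitted_mu, self.local_alpha
        if kind == "pearson":
            return (y - mu) / np.sqrt(mu + a * mu**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        d = 2 * (term - (y + 1 / a) * np.log((1 + a * y) / (1 + a * mu)))
        return np.sign(y - mu) * np.sqrt(np.maximum(d, 0.0))

    def coefficient_table(self, significance_level: float = 0.05) -> pd.DataFrame:
        """Long-format per-unit local estimates with significance flags."""
        rows = []
        crit = stats.norm.ppf(1 - significance_level / 2)
        for j, term in enumerate(self.terms):
            for i, uid in enumerate(self.units_index):
                t = self.local_beta[i, j] / self.local_se[i, j]
                rows.append(
                    {
                        "unit_id": uid,
                        "term": term,
                        "estimate": self.local_beta[i, j],
                        "SE": self.local_se[i, j],
                        "t": t,
                        "significant": bool(abs(t) > crit),
                    }
                )
        return pd.DataFrame(rows)

    def local_summary(self) -> pd.DataFrame:
        """Five-number summary (Min/LQ/Median/UQ/Max) of each local coefficient."""
        q = np.percentile(self.local_beta, [0, 25, 50, 75, 100], axis=0)
        return pd.DataFrame(
            q.T, index=self.terms, columns=["Min", "LQ", "Median", "UQ", "Max"]
        )


@dataclass
class BandwidthSearchResult:
    criterion: Literal["aic", "cv"]
    evaluated: list[tuple[float, float]]
    optimum: float
    tolerance: float
    bounds: tuple[float, float]

    def __post_init__(self) -> None:
        scores = dict(self.evaluated)
        if scores and scores[self.optimum] > min(scores.values()) + 1e-12:
            raise GWCrashError("search invariant violated: optimum is not the best probe")


# -- local estimation ----------------------------------------------------------


def local_loglikelihood(state: LocalFitState, beta: np.ndarray, alpha: float) -> float:
    """Kernel-weighted NB2 log-likelihood at (beta, alpha) for one focal unit."""
    mu = np.exp(state.log_t + state.X @ beta)
    return float(np.sum(state.w * nb2_loglik_terms(state.y, mu, alpha)))


def _weighted_ll(y, X, log_t, w, beta, alpha) -> float:
    mu = np.exp(log_t + X @ beta)
    return float(np.sum(w * nb2_loglik_terms(y, mu, alpha)))


def fit_local(
    state: LocalFitState,
    beta0: Optional[np.ndarray] = None,
    alpha0: float = 0.5,
    fix_alpha: bool = False,
    tol: float = 1e-8,
    max_outer: int = 100,
) -> LocalFitResult:
    """Maximize the local weighted NB2 likelihood at one focal unit.

    Alternates IRLS beta updates (with step-halving so the weighted
    likelihood never decreases) and bounded 1-D alpha updates until the
    weighted log-likelihood is stationary.
    """
    active = state.w > 0
    y, X, log_t, w = state.y[active], state.X[active], state.log_t[active], state.w[active]
    p = X.shape[1]
    if active.sum() < p + 2:
        raise GWCrashError(
            f"locally unidentified at focal {state.focal}: "
            f"{int(active.sum())} positive weights < p + 2 = {p + 2}"
        )
    if beta0 is None:
        beta = np.zeros(p)
        beta[0] = np.log(max(np.average(y, weights=w), 0.1)) - np.mean(log_t)
    else:
        beta = np.asarray(beta0, dtype=float).copy()
    alpha = float(alpha0)
    ll = _weighted_ll(y, X, log_t, w, beta, alpha)

    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_outer + 1):
        # (a) IRLS step for beta with step-halving
        mu = np.exp(log_t + X @ beta)
        A = mu / (1.0 + alpha * mu)
        z = (X @ beta) + (y - mu) / mu
        WA = w * A
        XtWA = X.T * WA
        M = XtWA @ X
        try:
            beta_new = np.linalg.solve(M, XtWA @ z)
        except np.linalg.LinAlgError as exc:
            raise GWCrashError(
                f"locally unidentified at focal {state.focal}: singular X'WAX"
            ) from exc
        step = beta_new - beta
        ll_new = -np.inf
        for _ in range(30):
            cand = beta + step
            with np.errstate(over="ignore"):
                eta = log_t + X @ cand
            if np.all(eta < 700):
                ll_new = _weighted_ll(y, X, log_t, w, cand, alpha)
                if ll_new >= ll - 1e-12:
                    break
            step *= 0.5
        else:
            cand, ll_new = beta, ll
        beta, ll_beta = cand, max(ll_new, ll)

        # (b) profile update of alpha
        if not fix_alpha:
            mu = np.exp(log_t + X @ beta)

            def neg(log_a: float) -> float:
                return -float(np.sum(w * nb2_loglik_terms(y, mu, np.exp(log_a))))

            opt = minimize_scalar(
                neg,
                bounds=(np.log(ALPHA_MIN), np.log(ALPHA_MAX)),
                method="bounded",
                options={"xatol": 1e-6},
            )
            if -opt.fun >= ll_beta - 1e-12:
                alpha = float(np.exp(opt.x))
                ll_new = -float(opt.fun)
            else:
                ll_new = ll_beta
        else:
            ll_new = ll_beta

        trace.append(ll_new)
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    mu = np.exp(log_t + X @ beta)
    A = mu / (1.0 + alpha * mu)
    M = (X.T * (w * A)) @ X
    try:
        cov = np.linalg.inv(M)
    except np.linalg.LinAlgError as exc:
        raise GWCrashError(
            f"locally unidentified at focal {state.focal}: singular X'WAX"
        ) from exc
    return LocalFitResult(
        beta=beta,
        alpha=alpha,
        cov=cov,
        loglik=ll,
        converged=converged,
        n_iterations=it,
        ll_trace=trace,
    )


def fit_gwnbr(
    units: SpatialUnitTable,
    covariates: Optional[Sequence[str]] = None,
    kernel: KernelSpec = KernelSpec("adaptive_bisquare", 50),
    offset: bool = True,
    global_alpha: bool = False,
    max_failure_fraction: float = 0.1,
) -> GWNBRFit:
    """Fit the spatially varying NB model at every unit's centroid.

    Every local fit warm-starts from the global NB estimates.  With
    ``global_alpha=True`` the dispersion is held at the global NB
    estimate instead of being re-estimated locally.  Per-unit failures
    are collected; more than ``max_failure_fraction`` of them aborts.
    """
    covs = list(covariates) if covariates is not None else list(units.covariates)
    X = units.design_matrix(covs)
    y = np.asarray(units.response_vector(), dtype=float)
    log_t = units.log_offset() if offset else np.zeros(units.n)
    n, p = X.shape
    if kernel.kind == "adaptive_bisquare" and kernel.bandwidth < p + 2:
        raise GWCrashError(
            f"adaptive bandwidth {kernel.bandwidth} below p + 2 = {p + 2}"
        )

    gfit = fit_negbin(units, covs, offset=offset)
    beta_g, alpha_g = gfit.params, gfit.alpha

    local_beta = np.empty((n, p))
    local_alpha = np.empty(n)
    local_se = np.empty((n, p))
    trace_s = 0.0
    conv = np.zeros(n, dtype=bool)
    failures: list[tuple[int, str]] = []
    for i in range(n):
        w = kernel_weight_vector(units, i, kernel)
        state = LocalFitState(focal=i, y=y, X=X, log_t=log_t, w=w)
        try:
            res = fit_local(
                state, beta0=beta_g, alpha0=alpha_g, fix_alpha=global_alpha
            )
        except GWCrashError as exc:
            failures.append((i, str(exc)))
            local_beta[i] = np.nan
            local_alpha[i] = np.nan
            local_se[i] = np.nan
            continue
        local_beta[i] = res.beta
        local_alpha[i] = res.alpha
        local_se[i] = np.sqrt(np.diag(res.cov))
        conv[i] = res.converged
        # hat contribution: w_ii = 1, a_ii from the converged local fit
        mu_i = np.exp(log_t[i] + X[i] @ res.beta)
        a_ii = mu_i / (1.0 + res.alpha * mu_i)
        trace_s += a_ii * float(X[i] @ res.cov @ X[i])

    if len(failures) > max_failure_fraction * n:
        msgs = "; ".join(f"unit {i}: {m}" for i, m in failures[:5])
        raise GWCrashError(
            f"{len(failures)}/{n} local fits failed (> {max_failure_fraction:.0%}): {msgs}"
        )

    fitted_mu = np.exp(log_t + np.einsum("ij,ij->i", X, local_beta))
    global_loglik = float(np.sum(nb2_loglik_terms(y, fitted_mu, local_alpha)))
    k_eff = trace_s + (1.0 if global_alpha else 0.0)
    return GWNBRFit(
        units_index=units.unit_ids,
        terms=["Intercept"] + covs,
        local_beta=local_beta,
        local_alpha=local_alpha,
        local_se=local_se,
        fitted_mu=fitted_mu,
        kernel=kernel,
        effective_params=k_eff,
        global_loglik=global_loglik,
        y=y,
        X=X,
        log_offset=log_t,
        global_alpha=global_alpha,
        per_unit_convergence=conv,
    )


# -- bandwidth selection -------------------------------------------------------


def golden_section_search(
    objective: Callable[[float], float],
    lo: float,
    hi: float,
    tol: float = 1.0,
    integer: bool = True,
    max_evals: int = 200,
) -> BandwidthSearchResult:
    """Golden-section minimization of a (presumed unimodal) objective.

    For integer (adaptive) bandwidths, probes are rounded to integers,
    every evaluation is cached, and the search stops once the bracket
    narrows to width <= 1; the best *evaluated* bandwidth is returned, so
    the reported optimum is never worse than any probe.
    """
    if not lo < hi:
        raise GWCrashError(f"invalid search bounds [{lo}, {hi}]")
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    cache: dict[float, float] = {}
    n_bad = 0

    def ev(b: float) -> float:
        b = float(round(b)) if integer else float(b)
        if b not in cache:
            nonlocal n_bad
            val = objective(b)
            if not np.isfinite(val):
                n_bad += 1
                if n_bad > max(1, len(cache) // 2):
                    raise GWCrashError(
                        f"objective non-finite at more than half of probes; "
                        f"evaluated: {sorted(cache)}"
                    )
                val = np.inf
            cache[b] = float(val)
        return cache[b]

    a, b = float(lo), float(hi)
    ev(a)
    ev(b)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = ev(c), ev(d)
    while (b - a) > (1.0 if integer else tol) and len(cache) < max_evals:
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = ev(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = ev(d)
        if integer and round(c) == round(d):
            # bracket collapsed onto one integer; probe its neighbours
            ev(max(lo, round(c) - 1))
            ev(min(hi, round(c) + 1))
            break
    best = min(cache, key=cache.get)
    return BandwidthSearchResult(
        criterion="aic",
        evaluated=sorted(cache.items()),
        optimum=best,
        tolerance=tol,
        bounds=(lo, hi),
    )


def _cv_score(
    units: SpatialUnitTable,
    covs: Sequence[str],
    kernel: KernelSpec,
    offset: bool,
    beta_g: np.ndarray,
    alpha_g: float,
) -> float:
    """Leave-one-out squared prediction error: focal weight forced to 0."""
    X = units.design_matrix(covs)
    y = np.asarray(units.response_vector(), dtype=float)
    log_t = units.log_offset() if offset else np.zeros(units.n)
    score = 0.0
    for i in range(units.n):
        w = kernel_weight_vector(units, i, kernel)
        w[i] = 0.0
        state = LocalFitState(focal=i, y=y, X=X, log_t=log_t, w=w)
        res = fit_local(state, beta0=beta_g, alpha0=alpha_g)
        yhat = np.exp(log_t[i] + X[i] @ res.beta)
        score += (y[i] - yhat) ** 2
    return float(score)


def select_bandwidth(
    units: SpatialUnitTable,
    covariates: Optional[Sequence[str]] = None,
    kernel_kind: str = "adaptive_bisquare",
    criterion: Literal["aic", "cv"] = "aic",
    bounds: Optional[tuple[float, float]] = None,
    tol: float = 1.0,
    offset: bool = True,
    global_alpha: bool = False,
) -> BandwidthSearchResult:
    """Golden-section bandwidth selection under AIC or leave-one-out CV.

    Default adaptive bounds are [max(p + 2, ceil(0.1 n)), n].  With
    ``global_alpha=True`` the AIC objective evaluates fits whose
    dispersion is held at the global NB estimate; the trace-of-S
    complexity then accounts for all of the model's local flexibility,
    which makes the AIC curve better behaved in b.
    """
    covs = list(covariates) if covariates is not None else list(units.covariates)
    p = len(covs) + 1
    n = units.n
    integer = kernel_kind == "adaptive_bisquare"
    if bounds is None:
        if not integer:
            raise GWCrashError("bounds are required for fixed kernels")
        bounds = (max(p + 2, int(np.ceil(0.1 * n))), n)
    lo, hi = bounds
    if integer and (lo < p + 2 or hi > n):
        raise GWCrashError(f"adaptive bounds must lie within [p+2, n] = [{p + 2}, {n}]")

    gfit = fit_negbin(units, covs, offset=offset)

    if criterion == "aic":
        def objective(b: float) -> float:
            return fit_gwnbr(
                units, covs, KernelSpec(kernel_kind, b),
                offset=offset, global_alpha=global_alpha,
            ).aic
    elif criterion == "cv":
        def objective(b: float) -> float:
            return _cv_score(
                units, covs, KernelSpec(kernel_kind, b), offset, gfit.params, gfit.alpha
            )
    else:
        raise GWCrashError(f"unknown criterion {criterion!r}")

    res = golden_section_search(objective, lo, hi, tol=tol, integer=integer)
    res.criterion = criterion
    return res
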