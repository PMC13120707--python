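"""Goodness-of-fit metrics and model-comparison tables.

AIC = -2 ln(Lhat) + 2k, MAD = mean absolute deviation of fitted from
observed counts, RMSE = root mean squared deviation.  Lower is better for
all three.  The comparison table also reports the global Moran's I of
each model's residuals: a well-specified spatial model should leave no
significant spatial autocorrelation behind.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .autocorr import MoranResult, global_moran
from .glm import GlobalFit
from .gwnbr import GWNBRFit
from .types import GWCrashError
from .weights import WeightMatrix

AnyFit = Union[GlobalFit, GWNBRFit]


@dataclass
class FitMetrics:
    label: str
    log_likelihood: float
    k: float
    aic: float
    mad: float
    rmse: float
    residual_moran: Optional[MoranResult] = None


def compute_metrics(
    y: np.ndarray, y_hat: np.ndarray, loglik: float, k: float, label: str = ""
) -> FitMetrics:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise GWCrashError(f"length mismatch: y {y.shape} vs y_hat {y_hat.shape}")
    if len(y) < 1 or k < 0:
        raise GWCrashError("need n >= 1 observations and k >= 0")
    mad = float(np.mean(np.abs(y_hat - y)))
    rmse = float(np.sqrt(np.mean((y_hat - y) ** 2)))
    assert rmse >= mad >= 0.0, "quadratic mean must dominate arithmetic mean"
    return FitMetrics(
        label=label,
        log_likelihood=float(loglik),
        k=float(k),
        aic=-2.0 * float(loglik) + 2.0 * float(k),
        mad=mad,
        rmse=rmse,
    )


def _fit_fields(fit: AnyFit) -> tuple[str, np.ndarray, np.ndarray, float, float]:
    if isinstance(fit, GWNBRFit):
        return ("gwnbr", fit.y, fit.fitted_mu, fit.global_loglik, fit.effective_params)
    return (fit.family, fit.y, fit.fitted_mu, fit.log_likelihood, float(fit.k))


def metrics_for_fit(fit: AnyFit, label: Optional[str] = None) -> FitMetrics:
    fam, y, mu, ll, k = _fit_fields(fit)
    return compute_metrics(y, mu, ll, k, label=label or fam)


def compare_models(
    fits: Sequence[AnyFit],
    wm: Optional[WeightMatrix] = None,
    labels: Optional[Sequence[str]] = None,
    residual_kind: str = "deviance",
    n_permutations: int = 0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """One row per model: Likelihood, AIC, RMSE, MAD (+ residual Moran).

    All fits must be on identical data; the best-AIC row is flagged.
    """
    if not fits:
        raise GWCrashError("no fits to compare")
    y0 = _fit_fields(fits[0])[1]
    rows = []
    for idx, fit in enumerate(fits):
        fam, y, mu, ll, k = _fit_fields(fit)
        if len(y) != len(y0) or not np.array_equal(y, y0):
            raise GWCrashError(f"fit {idx} ({fam}) is not on the same response data")
        label = labels[idx] if labels else fam
        m = compute_metrics(y, mu, ll, k, label=label)
        row = {
            "Models": m.label,
            "Likelihood": m.log_likelihood,
            "k": m.k,
            "AIC": m.aic,
            "RMSE": m.rmse,
            "MAD": m.mad,
        }
        if isinstance(fit, GWNBRFit):
            row["Type"] = f"{fit.kernel.kind}"
            row["Bandwidth"] = fit.kernel.bandwidth
        else:
            row["Type"] = "-"
            row["Bandwidth"] = np.nan
        if wm is not None:
            resid = fit.residuals(kind=residual_kind)
            mor = global_moran(resid, wm, n_permutations=n_permutations, seed=seed)
            row["residual_moran_I"] = mor.I
            row["residual_moran_p"] = (
                mor.p_permutation if mor.p_permutation is not None else mor.p_analytic
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    cols = ["Models", "Type", "Bandwidth", "Likelihood", "AIC", "RMSE", "MAD"]
    cols += [c for c in table.columns if c not in cols and c != "k"] + ["k"]
    table = table[cols]
    table["best_aic"] = table["AIC"] == table["AIC"].min()
    return table
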