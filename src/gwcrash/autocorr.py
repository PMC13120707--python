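"""Global and local spatial autocorrelation statistics.

Global Moran's I

    I = (N / W0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with W0 the sum of all weights, expectation E[I] = -1/(N-1) under the
null, analytic variance under either the randomization or the normality
assumption, and optional permutation inference.  Local Moran (LISA)
statistics classify each unit into High-High / Low-Low clusters and
Low-High / High-Low outliers, gated by a conditional-permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import GWCrashError
from .weights import WeightMatrix

#: Two-sided standard-normal critical value at the 99% confidence level,
#: the reference threshold for flagging a z-score as highly significant.
Z_CRITICAL_99 = float(stats.norm.ppf(1 - 0.01 / 2))


@dataclass
class MoranResult:
    I: float
    expected_I: float
    variance_I: float
    z_score: float
    p_analytic: float
    variance_assumption: Literal["randomization", "normality"]
    p_permutation: Optional[float] = None
    n_permutations: int = 0

    def summary(self) -> dict:
        return {
            "moran_I": self.I,
            "expected_I": self.expected_I,
            "variance_I": self.variance_I,
            "z_score": self.z_score,
            "p_analytic": self.p_analytic,
            "p_permutation": self.p_permutation,
        }


@dataclass
class LISAResult:
    ids: pd.Index
    local_I: np.ndarray
    z_local: np.ndarray
    p_local: np.ndarray
    cluster: np.ndarray  # strings in {HH, LL, LH, HL, NS}
    significance_level: float
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "local_I": self.local_I,
                "z_local": self.z_local,
                "p_local": self.p_local,
                "cluster": self.cluster,
            },
            index=self.ids,
        )


def _check_inputs(x: np.ndarray, wm: WeightMatrix) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) != wm.n:
        raise GWCrashError(
            f"variable length {x.shape} does not match weight matrix n={wm.n}"
        )
    if wm.n < 3:
        raise GWCrashError("Moran statistics require at least 3 units")
    if np.ptp(x) == 0:
        raise GWCrashError("zero variance: variable is constant")
    return x


def _moran_I(z: np.ndarray, wm: WeightMatrix) -> float:
    n = len(z)
    num = float(z @ (wm.W @ z))
    return (n / wm.s0) * num / float(z @ z)


def _moments(z: np.ndarray, wm: WeightMatrix, assumption: str) -> tuple[float, float]:
    """E[I] and Var[I] under the randomization or normality null."""
    n = len(z)
    W = wm.W
    s0 = wm.s0
    Wsym = W + W.T
    s1 = 0.5 * float((Wsym.multiply(Wsym)).sum())
    rc = np.asarray(W.sum(axis=1)).ravel() + np.asarray(W.sum(axis=0)).ravel()
    s2 = float(np.sum(rc**2))
    e_i = -1.0 / (n - 1)
    if assumption == "normality":
        var = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - e_i**2
    elif assumption == "randomization":
        b2 = n * np.sum(z**4) / np.sum(z**2) ** 2
        num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
            (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
        )
        var = num / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
    else:
        raise GWCrashError(f"unknown variance assumption {assumption!r}")
    return e_i, var


def expected_moran(n: int) -> float:
    """Null expectation of Moran's I for n spatial units: -1/(n-1)."""
    if n < 2:
        raise GWCrashError("need at least 2 units")
    return -1.0 / (n - 1)


def global_moran(
    x,
    wm: WeightMatrix,
    n_permutations: int = 0,
    seed: Optional[int] = None,
    variance_assumption: Literal["randomization", "normality"] = "randomization",
) -> MoranResult:
    """Global Moran's I with analytic and optional permutation inference.

    The permutation p-value is two-sided around E[I] and includes the
    observed statistic in both numerator and denominator:
    p = (1 + #{|I_perm - E| >= |I_obs - E|}) / (n_permutations + 1).
    """
    x = _check_inputs(x, wm)
    z = x - x.mean()
    I = _moran_I(z, wm)
    e_i, var = _moments(z, wm, variance_assumption)
    zscore = (I - e_i) / np.sqrt(var)
    p_analytic = 2 * stats.norm.sf(abs(zscore))
    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        dev = abs(I - e_i)
        count = 0
        for _ in range(n_permutations):
            I_p = _moran_I(rng.permutation(z), wm)
            if abs(I_p - e_i) >= dev:
                count += 1
        p_perm = (1 + count) / (n_permutations + 1)
    return MoranResult(
        I=I,
        expected_I=e_i,
        variance_I=var,
        z_score=zscore,
        p_analytic=float(p_analytic),
        variance_assumption=variance_assumption,
        p_permutation=p_perm,
        n_permutations=n_permutations,
    )


def local_moran(
    x,
    wm: WeightMatrix,
    n_permutations: int = 999,
    seed: Optional[int] = None,
    significance_level: float = 0.05,
    fdr: bool = False,
) -> LISAResult:
    """Local Moran statistics with conditional-permutation inference.

    local_I_i = (z_i / m2) * sum_j w_ij z_j with z the mean deviations and
    m2 = sum z^2 / n.  Under row-standardized weights the mean of the
    local statistics equals the global I.  The permutation scheme holds
    the focal value fixed and resamples neighbour values from the
    remaining n-1 observations.  Cluster labels come from the sign
    quadrant of (z_i, spatial lag of z_i), set to NS when the (optionally
    FDR-adjusted) p-value fails the significance gate.
    """
    x = _check_inputs(x, wm)
    if wm.style != "row_standardized":
        raise GWCrashError("local_moran expects a row-standardized weight matrix")
    n = wm.n
    z = x - x.mean()
    m2 = float(z @ z) / n
    lag = wm.W @ z
    local_I = z * lag / m2

    rng = np.random.default_rng(seed)
    p_local = np.ones(n)
    z_local = np.zeros(n)
    W = wm.W
    for i in range(n):
        sl = slice(W.indptr[i], W.indptr[i + 1])
        wvals = W.data[sl]
        k = len(wvals)
        if k == 0 or n_permutations <= 0:
            continue
        others = np.delete(z, i)
        # conditional permutation: draw k neighbour values per replicate
        draws = rng.random((n_permutations, len(others))).argpartition(k - 1, axis=1)[:, :k]
        lag_perm = others[draws] @ wvals
        I_perm = z[i] * lag_perm / m2
        count = int(np.sum(np.abs(I_perm) >= abs(local_I[i])))
        p_local[i] = (1 + count) / (n_permutations + 1)
        sd = I_perm.std(ddof=1)
        z_local[i] = (local_I[i] - I_perm.mean()) / sd if sd > 0 else 0.0

    p_gate = p_local.copy()
    if fdr:
        from statsmodels.stats.multitest import multipletests

        p_gate = multipletests(p_local, method="fdr_bh")[1]

    cluster = np.full(n, "NS", dtype=object)
    sig = p_gate < significance_level
    cluster[sig & (z > 0) & (lag > 0)] = "HH"
    cluster[sig & (z < 0) & (lag < 0)] = "LL"
    cluster[sig & (z < 0) & (lag > 0)] = "LH"
    cluster[sig & (z > 0) & (lag < 0)] = "HL"
    return LISAResult(
        ids=wm.ids,
        local_I=local_I,
        z_local=z_local,
        p_local=p_local,
        cluster=np.asarray(cluster),
        significance_level=significance_level,
        n_permutations=n_permutations,
    )
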