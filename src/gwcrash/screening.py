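"""Covariate screening: spatial-pattern retention and collinearity exclusion.

Two screens run before modelling.  The Moran screen flags covariates whose
global spatial autocorrelation is not significant (a spatially patternless
covariate cannot carry spatially varying structure).  The VIF screen drops
covariates whose variance inflation factor, VIF_k = 1/(1 - R^2_k) from
regressing column k on all the others plus an intercept, exceeds a
threshold — conventionally 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .autocorr import global_moran
from .types import GWCrashError, SpatialUnitTable
from .weights import WeightMatrix


@dataclass
class ScreeningReport:
    moran: pd.DataFrame = field(default_factory=pd.DataFrame)  # I, expected_I, z, p per variable
    vif: "pd.Series[float]" = field(default_factory=lambda: pd.Series(dtype=float))
    retained: list[str] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (variable, reason)

    def to_frame(self) -> pd.DataFrame:
        """Table mirroring a per-variable screening report (Moran + VIF + decision)."""
        variables = list(self.retained) + [v for v, _ in self.excluded]
        reasons = {v: r for v, r in self.excluded}
        rows = []
        for v in variables:
            row = {"variable": v}
            if v in self.moran.index:
                row.update(
                    moran_I=self.moran.loc[v, "I"],
                    expected_I=self.moran.loc[v, "expected_I"],
                    z=self.moran.loc[v, "z"],
                    p=self.moran.loc[v, "p"],
                )
            row["VIF"] = self.vif.get(v, np.nan)
            row["decision"] = f"excluded:{reasons[v]}" if v in reasons else "retained"
            rows.append(row)
        return pd.DataFrame(rows)


def compute_vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column.

    Perfectly collinear columns get +inf rather than raising.
    """
    X = pd.DataFrame(X)
    n, p = X.shape
    if n <= p + 1:
        raise GWCrashError(f"need more rows ({n}) than columns + 1 ({p + 1}) for VIF")
    out = {}
    M = X.to_numpy(dtype=float)
    for k, name in enumerate(X.columns):
        yk = M[:, k]
        if np.ptp(yk) == 0:
            raise GWCrashError(f"column {name!r} is constant")
        others = np.column_stack([np.ones(n), np.delete(M, k, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yk, rcond=None)
        resid = yk - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yk - yk.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def vif_screen(
    X: pd.DataFrame,
    threshold: float = 10.0,
    strategy: Literal["one_shot", "iterative"] = "one_shot",
) -> ScreeningReport:
    """Exclude covariates with VIF above ``threshold``.

    ``one_shot`` removes every offender at the initial VIFs in a single
    pass; ``iterative`` repeatedly removes the single worst offender and
    recomputes, which can retain variables a one-shot pass would drop.
    """
    X = pd.DataFrame(X)
    if threshold <= 1:
        raise GWCrashError("VIF threshold must exceed 1")
    excluded: list[tuple[str, str]] = []
    vif0 = compute_vif(X)
    if strategy == "one_shot":
        drop = vif0[vif0 > threshold].index.tolist()
        if len(drop) == len(X.columns):
            raise GWCrashError("empty model: every variable exceeded the VIF threshold")
        excluded = [(v, "vif_gt_threshold") for v in drop]
        retained = [c for c in X.columns if c not in drop]
    elif strategy == "iterative":
        current = list(X.columns)
        vif = vif0
        while True:
            over = vif[vif > threshold]
            if over.empty:
                break
            worst = over.idxmax()
            current.remove(worst)
            excluded.append((worst, "vif_gt_threshold"))
            if not current:
                raise GWCrashError("empty model: every variable exceeded the VIF threshold")
            if len(current) == 1:
                break
            vif = compute_vif(X[current])
        retained = current
    else:
        raise GWCrashError(f"unknown strategy {strategy!r}")
    return ScreeningReport(vif=vif0, retained=retained, excluded=excluded)


def moran_screen(
    units: SpatialUnitTable,
    variables: Sequence[str],
    wm: WeightMatrix,
    alpha: float = 0.05,
    n_permutations: int = 0,
    seed: Optional[int] = None,
    strict: bool = False,
) -> ScreeningReport:
    """Flag covariates whose global Moran p-value fails the significance gate.

    Advisory by default (flagged variables stay in ``retained`` with a
    recorded warning reason only under ``strict=True``).
    """
    rows, retained, excluded = {}, [], []
    for v in variables:
        res = global_moran(
            units.data[v].to_numpy(dtype=float), wm,
            n_permutations=n_permutations, seed=seed,
        )
        p = res.p_permutation if res.p_permutation is not None else res.p_analytic
        rows[v] = {"I": res.I, "expected_I": res.expected_I, "z": res.z_score, "p": p}
        if p >= alpha and strict:
            excluded.append((v, "moran_nonsignificant"))
        else:
            retained.append(v)
    return ScreeningReport(
        moran=pd.DataFrame.from_dict(rows, orient="index"),
        retained=retained,
        excluded=excluded,
    )


def screen_covariates(
    units: SpatialUnitTable,
    variables: Sequence[str],
    wm: WeightMatrix,
    vif_threshold: float = 10.0,
    moran_alpha: float = 0.05,
    strategy: Literal["one_shot", "iterative"] = "one_shot",
    strict_moran: bool = False,
    seed: Optional[int] = None,
) -> ScreeningReport:
    """Combined screen: Moran retention first, then VIF exclusion."""
    mrep = moran_screen(units, variables, wm, alpha=moran_alpha, strict=strict_moran, seed=seed)
    vrep = vif_screen(units.data[mrep.retained], threshold=vif_threshold, strategy=strategy)
    return ScreeningReport(
        moran=mrep.moran,
        vif=vrep.vif,
        retained=vrep.retained,
        excluded=mrep.excluded + vrep.excluded,
    )
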