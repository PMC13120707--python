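"""Core data container for zonal count analyses.

A :class:`SpatialUnitTable` holds one row per spatial unit (zone/district):
planar centroid coordinates, an optional polygon geometry, a nonnegative
integer response (crash counts), named real-valued covariate columns and an
optional positive exposure (offset) column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class GWCrashError(ValueError):
    """Base error for invalid inputs to the analysis pipeline."""


@dataclass
class SpatialUnitTable:
    """Table of spatial units with coordinates, response and covariates.

    Parameters
    ----------
    data
        One row per unit, indexed by a unique unit id, with planar
        centroid columns ``x`` and ``y`` plus any response/covariate
        columns.  Coordinates must be in a projected CRS so that
        Euclidean distance is meaningful.
    response
        Name of the count response column, if present.
    covariates
        Names of covariate columns used for modelling.
    offset
        Name of a positive exposure column entering the log link as
        ``ln(t)`` with coefficient fixed at 1, or ``None`` (t = 1).
    geometry
        Optional sequence of shapely polygons aligned with ``data``.
    crs
        Free-form description of the projected CRS of the coordinates.
    """

    data: pd.DataFrame
    response: Optional[str] = None
    covariates: list[str] = field(default_factory=list)
    offset: Optional[str] = None
    geometry: Optional[Sequence] = None
    crs: Optional[str] = None

    def __post_init__(self) -> None:
        if not {"x", "y"}.issubset(self.data.columns):
            raise GWCrashError("SpatialUnitTable requires 'x' and 'y' centroid columns")
        if not self.data.index.is_unique:
            raise GWCrashError("unit ids (index) must be unique")
        coords = self.data[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise GWCrashError("centroid coordinates must be finite")
        if self.response is not None:
            y = self.data[self.response].to_numpy()
            if np.any(y < 0) or not np.allclose(y, np.round(y)):
                raise GWCrashError(
                    f"response column {self.response!r} must hold nonnegative integers"
                )
        for c in self.covariates:
            if c not in self.data.columns:
                raise GWCrashError(f"covariate column {c!r} missing from data")
            if self.data[c].isna().any():
                raise GWCrashError(f"covariate column {c!r} contains missing values")
        if self.offset is not None:
            t = self.data[self.offset].to_numpy(dtype=float)
            if np.any(t <= 0):
                raise GWCrashError(f"offset column {self.offset!r} must be positive")
        if self.geometry is not None and len(self.geometry) != len(self.data):
            raise GWCrashError("geometry length does not match number of units")

    # -- convenience accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def unit_ids(self) -> pd.Index:
        return self.data.index

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of planar centroid coordinates."""
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def response_vector(self) -> np.ndarray:
        if self.response is None:
            raise GWCrashError("no response column declared")
        return self.data[self.response].to_numpy(dtype=float)

    def design_matrix(self, covariates: Optional[Sequence[str]] = None) -> np.ndarray:
        """Design matrix with a leading intercept column."""
        names = list(covariates) if covariates is not None else self.covariates
        X = np.column_stack(
            [np.ones(self.n)] + [self.data[c].to_numpy(dtype=float) for c in names]
        )
        return X

    def offset_vector(self) -> np.ndarray:
        """Exposure t per unit (defaults to 1)."""
        if self.offset is None:
            return np.ones(self.n)
        return self.data[self.offset].to_numpy(dtype=float)

    def log_offset(self) -> np.ndarray:
        return np.log(self.offset_vector())
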