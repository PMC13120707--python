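"""Spatial weight matrices and geographic kernels.

Two weighting notions live here:

* :class:`WeightMatrix` — the sparse n x n neighbour structure used by the
  Moran statistics (queen/rook contiguity, k-nearest-neighbour, inverse
  distance), optionally row-standardized.
* :class:`KernelSpec` / :func:`kernel_weight_vector` — the distance-decay
  weights used by locally weighted regression.  The adaptive bisquare
  kernel defines its bandwidth as a nearest-neighbour count, the fixed
  Gaussian kernel as a distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .types import GWCrashError, SpatialUnitTable


@dataclass
class WeightMatrix:
    """Sparse nonnegative spatial weights with a zero diagonal."""

    ids: pd.Index
    W: sparse.csr_matrix
    style: Literal["binary", "row_standardized"] = "binary"
    provenance: str = "custom"

    def __post_init__(self) -> None:
        self.W = sparse.csr_matrix(self.W)
        n = len(self.ids)
        if self.W.shape != (n, n):
            raise GWCrashError("weight matrix shape does not match ids")
        if self.W.diagonal().any():
            raise GWCrashError("weight matrix must have a zero diagonal")
        if self.W.nnz and (self.W.data < 0).any():
            raise GWCrashError("weights must be nonnegative")
        if self.W.nnz and not np.all(np.isfinite(self.W.data)):
            raise GWCrashError("weights must be finite")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def s0(self) -> float:
        """Sum of all weights (the W of the Moran denominator)."""
        return float(self.W.sum())

    def cardinalities(self) -> np.ndarray:
        return np.diff(self.W.indptr)

    def to_edge_list(self) -> pd.DataFrame:
        coo = self.W.tocoo()
        return pd.DataFrame(
            {
                "i_id": self.ids[coo.row],
                "j_id": self.ids[coo.col],
                "weight": coo.data,
            }
        )

    def to_csv(self, path) -> None:
        self.to_edge_list().to_csv(path, index=False)

    @classmethod
    def from_edge_list(
        cls, edges: pd.DataFrame, ids=None, style: str = "binary", provenance: str = "custom"
    ) -> "WeightMatrix":
        if ids is None:
            ids = pd.Index(pd.unique(pd.concat([edges["i_id"], edges["j_id"]])))
        else:
            ids = pd.Index(ids)
        pos = pd.Series(np.arange(len(ids)), index=ids)
        W = sparse.coo_matrix(
            (
                edges["weight"].to_numpy(dtype=float),
                (pos[edges["i_id"]].to_numpy(), pos[edges["j_id"]].to_numpy()),
            ),
            shape=(len(ids), len(ids)),
        ).tocsr()
        return cls(ids=ids, W=W, style=style, provenance=provenance)

    @classmethod
    def from_csv(cls, path, **kw) -> "WeightMatrix":
        return cls.from_edge_list(pd.read_csv(path), **kw)


def contiguity_weights(
    units: SpatialUnitTable, rule: Literal["queen", "rook"] = "queen"
) -> WeightMatrix:
    """Binary contiguity weights from polygon geometry.

    Queen: polygons sharing at least a boundary point are neighbours.
    Rook: polygons must share a boundary segment of positive length.
    Units without any neighbour (islands) trigger a warning and keep an
    empty row.
    """
    if units.geometry is None:
        raise GWCrashError("contiguity weights require polygon geometry for all units")
    missing = [str(uid) for uid, g in zip(units.unit_ids, units.geometry) if g is None]
    if missing:
        raise GWCrashError(f"units missing geometry: {missing}")
    if rule not in ("queen", "rook"):
        raise GWCrashError(f"unknown contiguity rule {rule!r}")

    from shapely.strtree import STRtree

    geoms = list(units.geometry)
    tree = STRtree(geoms)
    rows, cols = [], []
    for i, g in enumerate(geoms):
        for j in tree.query(g, predicate="intersects"):
            j = int(j)
            if j == i:
                continue
            inter = g.intersection(geoms[j])
            if inter.is_empty:
                continue
            if rule == "rook" and inter.length <= 0:
                continue
            rows.append(i)
            cols.append(j)
    n = units.n
    W = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    ).tocsr()
    card = np.diff(W.indptr)
    islands = units.unit_ids[card == 0]
    if len(islands):
        warnings.warn(
            f"{len(islands)} unit(s) have no {rule} neighbours (islands): "
            f"{list(map(str, islands[:10]))}",
            stacklevel=2,
        )
    return WeightMatrix(ids=units.unit_ids, W=W, style="binary", provenance=rule)


def knn_weights(units: SpatialUnitTable, k: int = 8) -> WeightMatrix:
    """Binary k-nearest-neighbour weights on centroid distance."""
    n = units.n
    if not 1 <= k < n:
        raise GWCrashError(f"k must be in [1, n-1]; got k={k}, n={n}")
    tree = cKDTree(units.coords)
    _, idx = tree.query(units.coords, k=k + 1)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    W = sparse.coo_matrix((np.ones(n * k), (rows, cols)), shape=(n, n)).tocsr()
    return WeightMatrix(ids=units.unit_ids, W=W, style="binary", provenance="knn")


def row_standardize(wm: WeightMatrix) -> WeightMatrix:
    """Divide each nonempty row by its sum; empty rows stay all-zero."""
    W = wm.W.tocsr(copy=True)
    rs = np.asarray(W.sum(axis=1)).ravel()
    scale = np.where(rs > 0, 1.0 / np.where(rs > 0, rs, 1.0), 0.0)
    W = sparse.diags(scale) @ W
    return WeightMatrix(
        ids=wm.ids, W=W.tocsr(), style="row_standardized", provenance=wm.provenance
    )


# -- geographic kernels --------------------------------------------------------


@dataclass(frozen=True)
class KernelSpec:
    """Distance-decay kernel for locally weighted regression.

    ``adaptive_bisquare`` interprets ``bandwidth`` as an integer
    nearest-neighbour count N_k (the focal unit counts as its own nearest
    neighbour at distance 0); ``fixed_gaussian`` interprets it as a
    positive distance.  ``uniform`` gives every unit weight 1 — the
    debug/limit kernel under which a locally weighted fit collapses to
    the global one.
    """

    kind: Literal["adaptive_bisquare", "fixed_gaussian", "uniform"] = "adaptive_bisquare"
    bandwidth: float = 50

    def __post_init__(self) -> None:
        if self.kind not in ("adaptive_bisquare", "fixed_gaussian", "uniform"):
            raise GWCrashError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "uniform":
            return
        if self.kind == "adaptive_bisquare":
            if self.bandwidth != int(self.bandwidth) or self.bandwidth < 2:
                raise GWCrashError("adaptive bandwidth must be an integer >= 2")
        elif self.bandwidth <= 0:
            raise GWCrashError("fixed bandwidth must be a positive distance")


def kernel_weight_vector(
    units: SpatialUnitTable, focal: int, spec: KernelSpec
) -> np.ndarray:
    """Kernel weights of every unit relative to the focal unit.

    Adaptive bisquare: with b the distance from the focal unit to its
    N_k-th nearest unit, w_j = (1 - (d_j/b)^2)^2 for d_j < b, else 0.
    Units exactly at distance b (ties) get weight 0, deterministically.
    Fixed Gaussian: w_j = exp(-(d_j/b)^2 / 2).  The focal unit always has
    weight 1.
    """
    coords = units.coords
    n = units.n
    if not 0 <= focal < n:
        raise GWCrashError(f"focal index {focal} out of range")
    if spec.kind == "uniform":
        return np.ones(n)
    d = np.linalg.norm(coords - coords[focal], axis=1)
    if spec.kind == "adaptive_bisquare":
        nk = int(spec.bandwidth)
        if nk > n:
            raise GWCrashError(f"adaptive bandwidth N_k={nk} exceeds n={n}")
        b = np.partition(d, nk - 1)[nk - 1]
        if b <= 0:
            dup = units.unit_ids[d == 0]
            raise GWCrashError(
                f"bandwidth distance is zero at unit {units.unit_ids[focal]!r}; "
                f"coincident units: {list(map(str, dup))}"
            )
        w = np.where(d < b, (1.0 - (d / b) ** 2) ** 2, 0.0)
    else:
        b = float(spec.bandwidth)
        w = np.exp(-0.5 * (d / b) ** 2)
    w[focal] = 1.0
    return w
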