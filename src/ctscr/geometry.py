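"""Discretized spatial domain and trap-array geometry.

The study region ``B`` is represented as a regular grid of square cells used
as a midpoint quadrature rule for every spatial integral in the model
(the expected population size ``Λ(B)`` and the never-detected probability
``π0``).  Cells flagged as non-habitat are excluded from all integrals and
from activity-center proposals and predictions.  Coordinates are planar
(projected) units; no geographic CRS handling is done here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Domain",
    "TrapArray",
    "build_grid",
    "squared_distances",
    "read_grid_csv",
    "write_grid_csv",
    "read_traps_csv",
    "write_traps_csv",
]


class DomainError(ValueError):
    """Raised for empty or inconsistent spatial domains."""


@dataclass
class Domain:
    """Regular-grid discretization of the study region.

    Parameters
    ----------
    cell_centers : (M, 2) array
        Midpoints of every grid cell (habitat or not), row-major over the
        grid (x fastest).
    cell_area : float
        Common area of a single cell, in squared coordinate units.
    mask : (M,) bool array
        True for habitat cells; non-habitat cells are excluded from all
        integrals and from center proposals.
    v : (M, p) array
        Per-cell density-covariate vectors; column 0 is the intercept
        regressor and must equal 1 everywhere.
    bounds : (xmin, ymin, xmax, ymax)
        Rectangle containing all cells.
    """

    cell_centers: np.ndarray
    cell_area: float
    mask: np.ndarray
    v: np.ndarray
    bounds: tuple[float, float, float, float]
    # regular-grid bookkeeping for O(1) point-to-cell lookup
    nx: int = field(default=0)
    ny: int = field(default=0)
    resolution: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.cell_centers = np.asarray(self.cell_centers, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.v = np.asarray(self.v, dtype=float)
        if self.cell_centers.ndim != 2 or self.cell_centers.shape[1] != 2:
            raise DomainError("cell_centers must be an (M, 2) array")
        m = self.cell_centers.shape[0]
        if self.mask.shape != (m,):
            raise DomainError("mask length must match the number of cells")
        if self.v.ndim != 2 or self.v.shape[0] != m:
            raise DomainError("covariate matrix must be (M, p)")
        if not np.allclose(self.v[:, 0], 1.0):
            raise DomainError("first covariate column must be the intercept (all ones)")
        if self.cell_area <= 0:
            raise DomainError("cell_area must be positive")
        if not self.mask.any():
            raise DomainError("domain has zero unmasked (habitat) cells")

    # -- derived geometry ---------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.cell_centers.shape[0]

    @property
    def n_active(self) -> int:
        return int(self.mask.sum())

    @property
    def active_centers(self) -> np.ndarray:
        return self.cell_centers[self.mask]

    @property
    def active_v(self) -> np.ndarray:
        return self.v[self.mask]

    @property
    def n_covariates(self) -> int:
        return self.v.shape[1]

    @property
    def total_area(self) -> float:
        """Area of the habitat (unmasked) region."""
        return float(self.cell_area * self.n_active)

    @property
    def diameter(self) -> float:
        xmin, ymin, xmax, ymax = self.bounds
        return float(np.hypot(xmax - xmin, ymax - ymin))

    # -- point lookups ------------------------------------------------------

    def cell_index_of(self, points: np.ndarray) -> np.ndarray:
        """Full-grid cell index of each point; -1 for points outside bounds."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        xmin, ymin, _, _ = self.bounds
        ix = np.floor((pts[:, 0] - xmin) / self.resolution).astype(int)
        iy = np.floor((pts[:, 1] - ymin) / self.resolution).astype(int)
        # points sitting exactly on the max edge belong to the last cell
        ix = np.where(ix == self.nx, self.nx - 1, ix)
        iy = np.where(iy == self.ny, self.ny - 1, iy)
        idx = iy * self.nx + ix
        outside = (ix < 0) | (ix >= self.nx) | (iy < 0) | (iy >= self.ny)
        return np.where(outside, -1, idx)

    def is_habitat(self, points: np.ndarray) -> np.ndarray:
        idx = self.cell_index_of(points)
        ok = idx >= 0
        res = np.zeros(idx.shape, dtype=bool)
        res[ok] = self.mask[idx[ok]]
        return res

    def covariates_at(self, points: np.ndarray) -> np.ndarray:
        """Density covariates v(s) at continuous locations (nearest-cell)."""
        idx = self.cell_index_of(points)
        if np.any(idx < 0):
            raise DomainError("point outside domain bounds")
        return self.v[idx]


@dataclass
class TrapArray:
    """Fixed detector locations with operating durations and covariates."""

    locations: np.ndarray  # (K, 2)
    durations: np.ndarray  # (K,) operating time T_k
    w: np.ndarray | None = None  # (K, p_w), column 0 = intercept
    ids: Sequence | None = None

    def __post_init__(self) -> None:
        self.locations = np.atleast_2d(np.asarray(self.locations, dtype=float))
        self.durations = np.atleast_1d(np.asarray(self.durations, dtype=float))
        if self.locations.shape[1] != 2:
            raise ValueError("trap locations must be (K, 2)")
        k = self.locations.shape[0]
        if k < 1:
            raise ValueError("at least one trap is required")
        if self.durations.shape == (1,) and k > 1:
            self.durations = np.full(k, self.durations[0])
        if self.durations.shape != (k,):
            raise ValueError("durations must have one entry per trap")
        if np.any(self.durations <= 0):
            raise ValueError("all trap durations T_k must be positive")
        if self.w is None:
            self.w = np.ones((k, 1))
        self.w = np.atleast_2d(np.asarray(self.w, dtype=float))
        if self.w.shape[0] != k:
            raise ValueError("trap covariates must be (K, p_w)")
        if not np.allclose(self.w[:, 0], 1.0):
            raise ValueError("first trap-covariate column must be the intercept")
        if self.ids is None:
            self.ids = list(range(k))

    @property
    def n_traps(self) -> int:
        return self.locations.shape[0]


def build_grid(
    bounds: tuple[float, float, float, float],
    resolution: float,
    mask_predicate: Callable[[np.ndarray], np.ndarray] | None = None,
    covariate_fields: Sequence[Callable[[np.ndarray], np.ndarray]] | None = None,
) -> Domain:
    """Tile a rectangle with square cells of side ``resolution``.

    ``mask_predicate`` maps an (M, 2) array of cell centers to a boolean
    habitat indicator; ``covariate_fields`` is a sequence of callables each
    mapping cell centers to one covariate column (the intercept column is
    prepended automatically).
    """
    xmin, ymin, xmax, ymax = bounds
    if resolution <= 0:
        raise DomainError("resolution must be positive")
    if xmax <= xmin or ymax <= ymin:
        raise DomainError("bounds rectangle is degenerate")
    nx = int(np.ceil((xmax - xmin) / resolution - 1e-9))
    ny = int(np.ceil((ymax - ymin) / resolution - 1e-9))
    xs = xmin + resolution * (np.arange(nx) + 0.5)
    ys = ymin + resolution * (np.arange(ny) + 0.5)
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    mask = (
        np.ones(centers.shape[0], dtype=bool)
        if mask_predicate is None
        else np.asarray(mask_predicate(centers), dtype=bool)
    )
    if not mask.any():
        raise DomainError("domain has zero unmasked (habitat) cells")
    cols = [np.ones(centers.shape[0])]
    if covariate_fields is not None:
        for f in covariate_fields:
            cols.append(np.asarray(f(centers), dtype=float).reshape(-1))
    v = np.column_stack(cols)
    return Domain(
        cell_centers=centers,
        cell_area=resolution**2,
        mask=mask,
        v=v,
        bounds=(xmin, ymin, xmin + nx * resolution, ymin + ny * resolution),
        nx=nx,
        ny=ny,
        resolution=resolution,
    )


def squared_distances(domain: Domain, traps: TrapArray) -> np.ndarray:
    """Squared Euclidean distance from every habitat cell center to every trap.

    Returns an (M_active, K) matrix; entry (m, k) is ``||c_m - x_k||^2``.
    """
    xmin, ymin, xmax, ymax = domain.bounds
    loc = traps.locations
    if np.any(loc[:, 0] < xmin) or np.any(loc[:, 0] > xmax) or np.any(
        loc[:, 1] < ymin
    ) or np.any(loc[:, 1] > ymax):
        raise ValueError("trap locations must lie within the domain bounds")
    c = domain.active_centers
    diff = c[:, None, :] - loc[None, :, :]
    return np.einsum("mkj,mkj->mk", diff, diff)


# -- CSV I/O (schemas: cell_id,x,y,mask,v1.. / trap_id,x,y,T,w1..) ----------


def write_grid_csv(domain: Domain, path) -> None:
    p = domain.n_covariates
    df = pd.DataFrame(
        {
            "cell_id": np.arange(domain.n_cells),
            "x": domain.cell_centers[:, 0],
            "y": domain.cell_centers[:, 1],
            "mask": domain.mask.astype(int),
        }
    )
    for j in range(p):
        df[f"v{j + 1}"] = domain.v[:, j]
    df.to_csv(path, index=False)


def read_grid_csv(path) -> Domain:
    df = pd.read_csv(path)
    required = {"cell_id", "x", "y", "mask"}
    if not required.issubset(df.columns):
        raise DomainError(f"grid file must contain columns {sorted(required)}")
    vcols = sorted(
        (c for c in df.columns if c.startswith("v") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    xs = np.sort(df["x"].unique())
    ys = np.sort(df["y"].unique())
    dx = np.diff(xs)
    res = float(dx.min()) if dx.size else float(np.diff(ys).min())
    # re-sort into row-major grid order
    df = df.sort_values(["y", "x"], kind="mergesort").reset_index(drop=True)
    centers = df[["x", "y"]].to_numpy(float)
    v = df[vcols].to_numpy(float) if vcols else np.ones((len(df), 1))
    return Domain(
        cell_centers=centers,
        cell_area=res**2,
        mask=df["mask"].to_numpy(bool),
        v=v,
        bounds=(
            float(xs.min() - res / 2),
            float(ys.min() - res / 2),
            float(xs.max() + res / 2),
            float(ys.max() + res / 2),
        ),
        nx=len(xs),
        ny=len(ys),
        resolution=res,
    )


def write_traps_csv(traps: TrapArray, path) -> None:
    df = pd.DataFrame(
        {
            "trap_id": traps.ids,
            "x": traps.locations[:, 0],
            "y": traps.locations[:, 1],
            "T": traps.durations,
        }
    )
    for j in range(traps.w.shape[1]):
        df[f"w{j + 1}"] = traps.w[:, j]
    df.to_csv(path, index=False)


def read_traps_csv(path) -> TrapArray:
    df = pd.read_csv(path)
    required = {"trap_id", "x", "y", "T"}
    if not required.issubset(df.columns):
        raise ValueError(f"trap file must contain columns {sorted(required)}")
    wcols = sorted(
        (c for c in df.columns if c.startswith("w") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    w = df[wcols].to_numpy(float) if wcols else None
    return TrapArray(
        locations=df[["x", "y"]].to_numpy(float),
        durations=df["T"].to_numpy(float),
        w=w,
        ids=df["trap_id"].tolist(),
    )
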