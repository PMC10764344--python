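"""Site- and grid-level predictor construction.

Builds the landscape covariates the occupancy models consume: CPI-adjusted
per-area residential land value averaged in buffers around each site,
buffered impervious-surface percentage, elevation, slope-weighted cost
distance to the ocean, Euclidean distance to natural areas (protected
polygons of at least 10 ha), and z-score standardization with persisted
parameters so grids can be transformed exactly as the sites were.

All coordinates live in a projected metric CRS with km units; grid
resolution defaults to 1 km.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra
from shapely.geometry import Point
from shapely.ops import unary_union

from .rasters import Raster

RESIDENTIAL = "residential"
MIN_PROTECTED_AREA_HA = 10.0
HA_PER_KM2 = 100.0


# ---------------------------------------------------------------------------
# Parcels and buffers
# ---------------------------------------------------------------------------

def normalize_parcels(parcels: pd.DataFrame, cpi: dict, cpi_now: float,
                      min_value: float | None = None) -> tuple[pd.DataFrame, dict]:
    """Residential parcels, CPI-scaled to current value, per unit area.

    ``cpi`` maps assessment year to index value and must cover every year in
    the table.  Values are multiplied by ``cpi_now / cpi[year]`` and divided
    by parcel area; rows whose per-area value falls below ``min_value``
    (default: the 1st percentile) are filtered as unreasonably low.
    """
    df = parcels.copy()
    if (df["area"] <= 0).any():
        raise ValueError("parcel areas must be positive")
    missing = sorted(set(df["year_assessed"]) - set(cpi))
    if missing:
        raise KeyError(f"CPI index missing for years {missing}")
    n_in = len(df)
    df = df[df["use_type"] == RESIDENTIAL].copy()
    n_nonres = n_in - len(df)
    factor = df["year_assessed"].map(cpi)
    df["value_per_area"] = df["assessed_value"] * (cpi_now / factor) / df["area"]
    if min_value is None:
        min_value = float(np.percentile(df["value_per_area"], 1)) if len(df) else 0.0
    low = df["value_per_area"] < min_value
    df = df[~low].reset_index(drop=True)
    ledger = {"input": n_in, "removed_non_residential": n_nonres,
              "removed_low_value": int(low.sum()), "min_value": float(min_value),
              "output": len(df)}
    return df, ledger


def buffer_mean(values, site_xy: tuple[float, float], radius_km: float,
                value_column: str = "value_per_area") -> float:
    """Mean of values within a circular buffer around a site.

    ``values`` is either a parcel table with x/y centroids (membership by
    centroid-in-buffer) or a :class:`Raster` (membership by cell center).
    Returns NaN with a warning when the buffer is empty.
    """
    sx, sy = site_xy
    if isinstance(values, Raster):
        gx, gy = values.cell_centers()
        inside = (gx - sx) ** 2 + (gy - sy) ** 2 <= radius_km ** 2
        member = values.data[inside]
        member = member[~np.isnan(member)]
    else:
        d2 = (values["x"] - sx) ** 2 + (values["y"] - sy) ** 2
        member = values.loc[d2 <= radius_km ** 2, value_column].to_numpy()
    if member.size == 0:
        warnings.warn(f"empty buffer at ({sx:.2f}, {sy:.2f}), r={radius_km}")
        return float("nan")
    return float(np.mean(member))


# ---------------------------------------------------------------------------
# Cost distance to the ocean
# ---------------------------------------------------------------------------

def slope_cost(slope: Raster) -> Raster:
    """Traversal cost surface: 1 + slope, so flat terrain still accrues distance."""
    return Raster(1.0 + slope.data, slope.xll, slope.yll, slope.cellsize)


def cost_distance(cost: Raster, source_mask: np.ndarray) -> Raster:
    """Least accumulated cost from any source cell, 8-connected.

    A step between adjacent cells costs the step length (cellsize, times
    sqrt(2) diagonally) times the mean of the two endpoint cell costs;
    source cells cost 0.  Cells cut off by infinite/NaN cost come back as
    +inf with a warning.
    """
    c = cost.data
    nrows, ncols = c.shape
    source_mask = np.asarray(source_mask, dtype=bool)
    if source_mask.shape != c.shape:
        raise ValueError("source mask and cost raster shapes differ")
    if not source_mask.any():
        raise ValueError("source mask is empty")
    n = nrows * ncols
    cflat = c.ravel()
    rows_idx, cols_idx, weights = [], [], []
    steps = [(-1, 0, 1.0), (1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0),
             (-1, -1, np.sqrt(2)), (-1, 1, np.sqrt(2)),
             (1, -1, np.sqrt(2)), (1, 1, np.sqrt(2))]
    idx = np.arange(n).reshape(nrows, ncols)
    for dr, dc, length in steps:
        r0, r1 = max(0, -dr), min(nrows, nrows - dr)
        c0, c1 = max(0, -dc), min(ncols, ncols - dc)
        a = idx[r0:r1, c0:c1].ravel()
        b = idx[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        w = length * cost.cellsize * 0.5 * (cflat[a] + cflat[b])
        ok = np.isfinite(w)
        rows_idx.append(a[ok])
        cols_idx.append(b[ok])
        weights.append(w[ok])
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows_idx), np.concatenate(cols_idx))),
        shape=(n, n),
    ).tocsr()
    sources = np.flatnonzero(source_mask.ravel())
    dist = _csgraph_dijkstra(graph, directed=True, indices=sources, min_only=True)
    dist[sources] = 0.0
    out = dist.reshape(nrows, ncols)
    if np.isinf(out).any():
        warnings.warn(f"{int(np.isinf(out).sum())} cells unreachable from the ocean")
    return Raster(out, cost.xll, cost.yll, cost.cellsize)


def cost_distance_to_ocean(slope: Raster, ocean_mask: Raster) -> Raster:
    """Accumulated slope-cost distance from the ocean source cells."""
    if not slope.same_grid(ocean_mask):
        raise ValueError("slope and ocean mask are not on the same grid")
    return cost_distance(slope_cost(slope), ocean_mask.data > 0)


# ---------------------------------------------------------------------------
# Distance to natural areas
# ---------------------------------------------------------------------------

def distance_to_natural_areas(polygons, grid: Raster,
                              min_area_ha: float = MIN_PROTECTED_AREA_HA,
                              areas_ha=None) -> Raster:
    """Per-cell Euclidean distance (km) to the nearest retained natural area.

    Protected-area polygons smaller than ``min_area_ha`` are discarded as
    manicured parks; cells inside a retained polygon get distance 0.  Areas
    are taken from ``areas_ha`` when given, else from polygon geometry
    (km^2 -> ha).
    """
    polygons = list(polygons)
    if areas_ha is None:
        areas_ha = [p.area * HA_PER_KM2 for p in polygons]
    kept = [p for p, a in zip(polygons, areas_ha) if a >= min_area_ha]
    if not kept:
        raise ValueError("no protected areas of at least "
                         f"{min_area_ha} ha remain")
    union = unary_union(kept)
    gx, gy = grid.cell_centers()
    out = np.empty(grid.shape)
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            out[i, j] = union.distance(Point(gx[i, j], gy[i, j]))
    return Raster(out, grid.xll, grid.yll, grid.cellsize)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizationParams:
    """Per-variable transform ('none' | 'log'), mean and SD on the site data."""

    transform: dict
    mean: dict
    sd: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"transform": self.transform, "mean": self.mean,
                             "sd": self.sd})


DEFAULT_TRANSFORMS = {"land_value": "log"}


def standardize(values: pd.DataFrame, transform_map: dict | None = None
                ) -> tuple[pd.DataFrame, StandardizationParams]:
    """Optionally log-transform, then z-score each column using its own
    mean/SD; the parameters are returned for reuse on prediction grids."""
    tmap = {c: (transform_map or DEFAULT_TRANSFORMS).get(c, "none")
            for c in values.columns}
    out = values.copy().astype(float)
    means, sds = {}, {}
    for col in values.columns:
        x = out[col]
        if tmap[col] == "log":
            if (x <= 0).any():
                raise ValueError(f"non-positive value under log transform: {col!r}")
            x = np.log(x)
        elif tmap[col] != "none":
            raise ValueError(f"unknown transform {tmap[col]!r} for {col!r}")
        mu, sd = float(x.mean()), float(x.std(ddof=0))
        if sd == 0:
            raise ValueError(f"constant variable cannot be standardized: {col!r}")
        out[col] = (x - mu) / sd
        means[col], sds[col] = mu, sd
    return out, StandardizationParams(tmap, means, sds)


def apply_standardization(values, params: StandardizationParams):
    """Transform new data (frame or dict of rasters) with stored parameters."""
    if isinstance(values, pd.DataFrame):
        out = values.copy().astype(float)
        for col in out.columns:
            out[col] = _apply_one(out[col].to_numpy(), col, params)
        return out
    return {name: Raster(_apply_one(r.data, name, params), r.xll, r.yll, r.cellsize)
            for name, r in values.items()}


def _apply_one(x, name, params: StandardizationParams):
    if name not in params.mean:
        raise KeyError(f"no standardization parameters stored for {name!r}")
    x = np.asarray(x, dtype=float)
    if params.transform[name] == "log":
        bad = x <= 0
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(bad, np.nan, np.log(np.where(bad, 1.0, x)))
    return (x - params.mean[name]) / params.sd[name]


def unstandardize(values: pd.DataFrame, params: StandardizationParams) -> pd.DataFrame:
    """Inverse of :func:`standardize` (for round-trip checks and reporting)."""
    out = values.copy().astype(float)
    for col in out.columns:
        x = out[col] * params.sd[col] + params.mean[col]
        if params.transform[col] == "log":
            x = np.exp(x)
        out[col] = x
    return out
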