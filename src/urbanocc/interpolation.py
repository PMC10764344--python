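"""Spatial projection of fitted occupancy and stacked richness maps.

The all-covariate model fitted at the sites is evaluated over a 1-km
predictor grid: bands are standardized with the *site*-derived parameters,
climate bands are re-centered onto the logger-derived site means (an
additive shift, assuming the gridded climatology scales linearly with the
site-level differences), cells beyond three standard deviations of the
site mean in any band are masked, and masking is contagious — a cell
missing any predictor is dropped from every output.

Richness per cell is the sum over species of the per-species posterior
median occupancy probability, accumulated by taxonomic group and in total;
it is an expected species count, bounded by the number of species modelled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .covariates import StandardizationParams, apply_standardization
from .occupancy import PosteriorDraws
from .rasters import Raster, write_ascii

SD_LIMIT = 3.0


@dataclass
class PredictionGrid:
    """Standardized predictor bands with a shared validity mask."""

    bands: dict
    mask: np.ndarray
    richness: dict = field(default_factory=dict)
    species_median: dict = field(default_factory=dict)

    @property
    def template(self) -> Raster:
        return next(iter(self.bands.values()))

    def design(self, terms) -> tuple[np.ndarray, np.ndarray]:
        """(cells x terms) design over valid cells, plus flat valid index."""
        valid = np.flatnonzero(self.mask.ravel())
        X = np.column_stack([self.bands[t].data.ravel()[valid] for t in terms])
        return X, valid


def recenter_band(band: Raster, site_values, site_cells) -> Raster:
    """Shift a grid band so its mean at the site cells matches the site data.

    ``site_values`` are the logger-derived site measurements and
    ``site_cells`` the (row, col) arrays of the corresponding grid cells.
    """
    rows, cols = site_cells
    at_sites = band.data[np.asarray(rows), np.asarray(cols)]
    shift = float(np.mean(site_values)) - float(np.nanmean(at_sites))
    return Raster(band.data + shift, band.xll, band.yll, band.cellsize)


def prepare_grid(stack: dict, params: StandardizationParams,
                 recenter: dict | None = None,
                 sd_limit: float = SD_LIMIT) -> PredictionGrid:
    """Standardize, re-center and mask the predictor stack.

    ``recenter`` maps band name -> (site_values, site_cells); the named
    bands are additively shifted before standardization.  Standardized
    values strictly beyond ``sd_limit`` become NaN, and any-band-missing
    masks the whole cell.
    """
    template = next(iter(stack.values()))
    for name, r in stack.items():
        if not r.same_grid(template):
            raise ValueError(f"band {name!r} is not aligned with the stack")
    missing = [n for n in stack if n not in params.mean]
    if missing:
        raise KeyError(f"no standardization parameters for bands {missing}")
    shifted = dict(stack)
    for name, (site_values, site_cells) in (recenter or {}).items():
        shifted[name] = recenter_band(shifted[name], site_values, site_cells)
    std = apply_standardization(shifted, params)
    for name, r in std.items():
        r.data[np.abs(r.data) > sd_limit] = np.nan
    mask = np.all([np.isfinite(r.data) for r in std.values()], axis=0)
    for r in std.values():
        r.data[~mask] = np.nan
    return PredictionGrid(bands=std, mask=mask)


def species_median_occupancy(draws: PosteriorDraws, grid: PredictionGrid) -> np.ndarray:
    """Per-species posterior median of psi at each valid cell, (S, n_valid)."""
    X, _ = grid.design(draws.terms)
    psi0 = draws.flat("psi0")  # (n,)
    a = draws.flat("a")  # (n, S)
    b = draws.flat("b")  # (n, S, P)
    if a.shape[1] != len(draws.species):
        raise ValueError("species/coefficient mismatch")
    S = a.shape[1]
    med = np.empty((S, X.shape[0]))
    for i in range(S):
        eta = psi0[None, :] + a[None, :, i] + X @ b[:, i, :].T  # (cells, n)
        med[i] = np.median(expit(eta), axis=1)
    return med


def predict_richness(draws_by_group, grid: PredictionGrid) -> PredictionGrid:
    """Stack per-species median occupancies into group and total richness.

    Accepts a single :class:`PosteriorDraws` (one group) or a mapping of
    group name -> draws; adds one richness raster per group plus 'total'.
    """
    if isinstance(draws_by_group, PosteriorDraws):
        name = draws_by_group.spec.group if draws_by_group.spec else "group"
        draws_by_group = {name: draws_by_group}
    template = grid.template
    _, valid = grid.design(next(iter(draws_by_group.values())).terms)
    total = np.zeros(len(valid))
    for group, draws in draws_by_group.items():
        med = species_median_occupancy(draws, grid)
        richness = med.sum(axis=0)
        total += richness
        grid.species_median[group] = med
        grid.richness[group] = _to_raster(richness, valid, template)
    grid.richness["total"] = _to_raster(total, valid, template)
    return grid


def richness_from_truth(truth, grid: PredictionGrid, terms=None) -> Raster:
    """Richness map from generating parameters (oracle for recovery checks)."""
    terms = tuple(terms) if terms is not None else truth.predictors
    X, valid = grid.design(terms)
    slopes = truth.species_slopes[list(terms)].to_numpy()
    eta = (truth.psi0 + truth.species_intercepts_psi[:, None]
           + slopes @ X.T)
    return _to_raster(expit(eta).sum(axis=0), valid, grid.template)


def _to_raster(values: np.ndarray, valid: np.ndarray, template: Raster) -> Raster:
    flat = np.full(template.data.size, np.nan)
    flat[valid] = values
    return Raster(flat.reshape(template.shape), template.xll, template.yll,
                  template.cellsize)


def write_maps(grid: PredictionGrid, out_dir, quicklook: bool = True) -> list:
    """Write one ASCII-grid raster per richness map plus metadata (and PNGs)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not grid.richness:
        raise ValueError("richness has not been computed")
    written = []
    for name, raster in grid.richness.items():
        path = out / f"richness_{name}.asc"
        write_ascii(raster, path)
        written.append(path)
        if quicklook:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(5, 4))
            im = ax.imshow(raster.data, cmap="viridis")
            fig.colorbar(im, ax=ax, label="expected species")
            ax.set_title(f"Projected richness: {name}")
            fig.savefig(out / f"richness_{name}.png", dpi=120)
            plt.close(fig)
    template = grid.template
    meta = {
        "crs": "projected metric, km units",
        "cellsize_km": template.cellsize,
        "shape": list(template.shape),
        "n_valid_cells": int(grid.mask.sum()),
        "groups": sorted(k for k in grid.richness if k != "total"),
    }
    with open(out / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    written.append(out / "metadata.json")
    return written
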