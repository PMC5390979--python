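"""Epanechnikov kernel density surfaces at 1 km² resolution.

Point observations (people, boats, tonnes) are spread over the area of
influence with the quadratic (Epanechnikov) kernel, maximum at the point
itself and support out to the bandwidth h (default 75 km, the fleet's
search radius). Because the points carry totals rather than sample
frequencies, the kernel is weighted by the point values and — in the
default ``mass_conserving`` mode — normalized so each point's total mass
is preserved on the surface: c(r) = (2/(πh²))·(1 − r²/h²), which
integrates to 1 over the disc of radius h. A ``paper_literal`` mode uses
the 1-D normalization (0.75/h)·(1 − r²/h²) instead; the two surfaces are
proportional, so everything downstream of a ratio (the allometric fit,
PFE shape) is unaffected by the choice.

The 1 km² pixel surface is aggregated to analysis cells as the per-cell
mean pixel density (pixel-center-in-cell membership), optionally rescaled
by cell area to cell totals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo_grid import CellValues, Grid, PointObservations

MODES = ("mass_conserving", "paper_literal")


@dataclass
class KdeConfig:
    bandwidth_h_km: float = 75.0
    resolution_km: float = 1.0
    mode: str = "mass_conserving"

    def __post_init__(self) -> None:
        if self.bandwidth_h_km <= 0:
            raise ValueError("bandwidth must be positive")
        if self.resolution_km <= 0:
            raise ValueError("resolution must be positive")
        if self.resolution_km > self.bandwidth_h_km:
            raise ValueError("resolution must not exceed bandwidth")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass
class DensityRaster:
    """Gridded density surface (input units per km²).

    ``matrix[i, j]`` is the density at pixel row i (south to north),
    column j (west to east); ``origin`` is the projected (x, y) of the
    raster's min corner in metres.
    """

    origin: tuple[float, float]
    resolution_km: float
    matrix: np.ndarray
    n_points: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.matrix).all():
            raise ValueError("non-finite densities")
        if (self.matrix < 0).any():
            raise ValueError("negative densities")

    @property
    def pixel_area_km2(self) -> float:
        return self.resolution_km**2

    def total_mass(self) -> float:
        """Integral of the surface: Σ pixels × pixel area (input units)."""
        return float(self.matrix.sum() * self.pixel_area_km2)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        res_m = self.resolution_km * 1000.0
        nrows, ncols = self.matrix.shape
        xs = self.origin[0] + (np.arange(ncols) + 0.5) * res_m
        ys = self.origin[1] + (np.arange(nrows) + 0.5) * res_m
        return xs, ys


def kernel_shape(r: np.ndarray | float, h: float) -> np.ndarray | float:
    """Epanechnikov profile ¾(1 − (r/h)²) on r ≤ h, else 0."""
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    r = np.asarray(r, dtype=float)
    if (r < 0).any():
        raise ValueError("distance must be non-negative")
    u = r / h
    out = np.where(u <= 1.0, 0.75 * (1.0 - u**2), 0.0)
    return float(out) if out.ndim == 0 else out


def _radial_scale(h_km: float, mode: str) -> float:
    # peak (r=0) value of the per-point kernel, per km²
    if mode == "mass_conserving":
        return 2.0 / (math.pi * h_km**2)
    return 0.75 / h_km  # paper_literal, 1-D normalization


def density_surface(
    points: PointObservations,
    cfg: KdeConfig,
    extent: tuple[float, float, float, float] | None = None,
) -> DensityRaster:
    """Weighted Epanechnikov KDE of point values over a pixel raster.

    ``extent`` is (minx, miny, maxx, maxy) in projected metres; when
    omitted it is the point bounding box. The raster pads the extent by
    the bandwidth so no kernel support is cut off at the declared extent.
    """
    h_m = cfg.bandwidth_h_km * 1000.0
    res_m = cfg.resolution_km * 1000.0
    if len(points) == 0:
        warnings.warn("no input points; returning an all-zero raster")
        if extent is None:
            extent = (0.0, 0.0, res_m, res_m)
    elif extent is None:
        xs, ys = points.xy[:, 0], points.xy[:, 1]
        extent = (xs.min(), ys.min(), xs.max(), ys.max())

    minx, miny, maxx, maxy = extent
    ox, oy = minx - h_m, miny - h_m
    ncols = max(1, math.ceil((maxx + h_m - ox) / res_m))
    nrows = max(1, math.ceil((maxy + h_m - oy) / res_m))
    matrix = np.zeros((nrows, ncols))
    peak = _radial_scale(cfg.bandwidth_h_km, cfg.mode)

    px = ox + (np.arange(ncols) + 0.5) * res_m
    py = oy + (np.arange(nrows) + 0.5) * res_m
    for (x, y), v in zip(points.xy, points.values):
        # pixel window covering the kernel support
        j0 = max(0, int((x - h_m - ox) // res_m))
        j1 = min(ncols, int((x + h_m - ox) // res_m) + 1)
        i0 = max(0, int((y - h_m - oy) // res_m))
        i1 = min(nrows, int((y + h_m - oy) // res_m) + 1)
        if j0 >= j1 or i0 >= i1:
            continue
        dx = (px[j0:j1] - x) / h_m
        dy = (py[i0:i1] - y) / h_m
        r2 = dy[:, None] ** 2 + dx[None, :] ** 2
        matrix[i0:i1, j0:j1] += v * peak * np.clip(1.0 - r2, 0.0, None)

    return DensityRaster(
        origin=(ox, oy),
        resolution_km=cfg.resolution_km,
        matrix=matrix,
        n_points=len(points),
    )


def aggregate_mean(
    raster: DensityRaster,
    grid: Grid,
    units: str = "",
    cell_totals: bool = False,
) -> CellValues:
    """Per-cell mean pixel density, or cell totals (mean × cell area).

    Pixel membership is by pixel center; cells covered by no pixel are
    absent from the result (with a warning).
    """
    xs, ys = raster.pixel_centers()
    side = grid.side_m
    cols = np.floor((xs - grid.origin[0]) / side).astype(int)
    rows = np.floor((ys - grid.origin[1]) / side).astype(int)
    col_ok = (cols >= 0) & (cols < grid.ncols)
    row_ok = (rows >= 0) & (rows < grid.nrows)

    cid = rows[:, None] * grid.ncols + cols[None, :]
    ok = row_ok[:, None] & col_ok[None, :]
    flat_ids = cid[ok]
    flat_vals = raster.matrix[ok]
    n_bins = grid.nrows * grid.ncols
    pix_sums = np.bincount(flat_ids, weights=flat_vals, minlength=n_bins)
    pix_counts = np.bincount(flat_ids, minlength=n_bins)

    grid_ids = np.array(grid.cell_ids)
    covered = pix_counts[grid_ids] > 0
    if (~covered).any():
        warnings.warn(f"{int((~covered).sum())} grid cell(s) covered by no raster pixel")
    ids = grid_ids[covered]
    series = pd.Series(
        pix_sums[ids] / pix_counts[ids], index=ids, dtype=float
    ).sort_index()
    if cell_totals:
        series = series * grid.cell_area_km2
    return CellValues(values=series, units=units)
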