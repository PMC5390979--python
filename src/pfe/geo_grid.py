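"""Area of influence, analysis grid, and point-to-cell assignment.

The working frame is always projected metres (UTM). The fished area
("area of influence") is the coastline buffered by the mean trip
distance of the fleet (75 km here); the analysis grid is a lattice of
congruent square cells (default 500 km², the estimated fishing area per
vessel) clipped to cells that intersect the area of influence. Raw point
observations — community populations, boat counts, landings — are summed
into the cell containing them ("raw data" on cell centroids).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, box
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform as shp_transform

from .projection import geographic_to_utm, utm_zone_from_lon


@dataclass
class Coastline:
    """A coastline geometry tagged with its coordinate reference.

    ``crs`` is either ``"geographic"`` (lon/lat degrees) or
    ``"projected"`` (metres); ``utm_zone`` records the zone once
    projected.
    """

    geometry: BaseGeometry
    crs: str = "geographic"
    utm_zone: int | None = None

    def __post_init__(self) -> None:
        if self.geometry is None or self.geometry.is_empty:
            raise ValueError("coastline geometry is empty")
        if self.crs not in ("geographic", "projected"):
            raise ValueError(f"unknown crs tag {self.crs!r}")


@dataclass
class AreaOfInfluence:
    polygon: BaseGeometry
    seaward_buffer_km: float = 75.0
    inland_buffer_km: float = 5.0

    def __post_init__(self) -> None:
        if self.polygon.area <= 0:
            raise ValueError("area of influence has zero area")
        if self.seaward_buffer_km <= 0:
            raise ValueError("seaward buffer must be positive")


@dataclass(frozen=True)
class GridCell:
    id: int
    row: int
    col: int
    polygon: Polygon
    centroid: tuple[float, float]


@dataclass
class Grid:
    """Axis-aligned square grid anchored at the AoI bounding-box min corner.

    Cell ids are ``row * ncols + col`` (0-based, row-major); only cells
    intersecting the area of influence are kept.
    """

    cell_area_km2: float
    origin: tuple[float, float]  # projected m, min corner
    side_m: float
    nrows: int
    ncols: int
    cells: list[GridCell] = field(default_factory=list)
    _by_id: dict[int, GridCell] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {c.id: c for c in self.cells}
        if len(self._by_id) != len(self.cells):
            raise ValueError("duplicate cell ids")

    @property
    def cell_ids(self) -> list[int]:
        return [c.id for c in self.cells]

    def cell(self, cell_id: int) -> GridCell:
        return self._by_id[cell_id]

    def locate(self, x: float, y: float) -> int | None:
        """Cell id containing projected point (x, y), or None.

        A point exactly on a shared edge goes to the lower (row, col)
        cell; points on the grid's outer min edge stay in row/col 0.
        """
        col = _edge_floor((x - self.origin[0]) / self.side_m)
        row = _edge_floor((y - self.origin[1]) / self.side_m)
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            return None
        cid = row * self.ncols + col
        return cid if cid in self._by_id else None

    def centroids(self, cell_ids: list[int] | None = None) -> np.ndarray:
        ids = self.cell_ids if cell_ids is None else cell_ids
        return np.array([self._by_id[i].centroid for i in ids])


def _edge_floor(t: float) -> int:
    """floor(t), but an exact lattice value > 0 belongs to the cell below."""
    f = math.floor(t)
    if t == f and f > 0:
        return f - 1
    return f


@dataclass
class PointObservations:
    """Point records {x, y (projected m), value, source tag}."""

    table: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        required = {"x", "y", "value"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        t = self.table
        if len(t) and (not np.isfinite(t[["x", "y"]].to_numpy()).all()):
            raise ValueError("non-finite coordinates")
        if len(t) and (t["value"] < 0).any():
            raise ValueError("negative observation values")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def xy(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.table["value"].to_numpy(dtype=float)


@dataclass
class CellValues:
    """Per-cell non-negative scalar field keyed by grid cell id."""

    values: pd.Series  # index: cell id
    units: str = ""

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if len(v) and not np.isfinite(v).all():
            raise ValueError("non-finite cell values")
        if len(v) and (v < 0).any():
            raise ValueError("negative cell values")
        self.values = pd.Series(v, index=self.values.index, name=self.units or "value")

    def aligned_with(self, other: "CellValues") -> tuple[np.ndarray, np.ndarray, pd.Index]:
        """Values of self and other on their shared cell ids."""
        common = self.values.index.intersection(other.values.index)
        return (
            self.values.loc[common].to_numpy(),
            other.values.loc[common].to_numpy(),
            common,
        )


def project_geometry(
    geometry: BaseGeometry, utm_zone: int | None = None
) -> tuple[BaseGeometry, int]:
    """Project a geographic (lon/lat) geometry to UTM metres.

    The zone is auto-derived from the geometry centroid's longitude when
    not given. Returns (projected geometry, zone used).
    """
    if geometry is None or geometry.is_empty:
        raise ValueError("cannot project an empty geometry")
    if not geometry.is_valid:
        raise ValueError("invalid geometry")
    if utm_zone is None:
        utm_zone = utm_zone_from_lon(geometry.centroid.x)

    def _fwd(x, y):
        return geographic_to_utm(x, y, utm_zone)

    return shp_transform(_fwd, geometry), utm_zone


def buffer_seaward(
    coastline: Coastline,
    distance_km: float,
    land: BaseGeometry | None = None,
) -> AreaOfInfluence:
    """Buffer the (projected) coastline by the fleet's mean trip distance.

    Without a land polygon the buffer is two-sided; with one, the land
    side is clipped off so only water within ``distance_km`` remains.
    """
    if distance_km <= 0:
        raise ValueError("buffer distance must be positive")
    if coastline.crs != "projected":
        raise ValueError("coastline must be projected before buffering")
    poly = coastline.geometry.buffer(distance_km * 1000.0, quad_segs=64)
    if land is not None:
        poly = poly.difference(land)
    return AreaOfInfluence(polygon=poly, seaward_buffer_km=distance_km)


def select_coastal_communities(
    communities: PointObservations,
    coastline: Coastline,
    inland_km: float = 5.0,
) -> PointObservations:
    """Keep communities within ``inland_km`` of the coastline (closed bound)."""
    if coastline.crs != "projected":
        raise ValueError("coastline must be projected")
    if len(communities) == 0:
        return communities
    geom = coastline.geometry
    d = shapely.distance(geom, shapely.points(communities.xy))
    keep = d <= inland_km * 1000.0
    return PointObservations(
        communities.table.loc[keep].reset_index(drop=True), source=communities.source
    )


def build_grid(aoi: AreaOfInfluence, cell_area_km2: float = 500.0) -> Grid:
    """Construct the analysis grid of congruent square cells over the AoI."""
    if cell_area_km2 <= 0:
        raise ValueError("cell area must be positive")
    if not aoi.polygon.is_valid:
        raise ValueError("invalid area-of-influence polygon")
    side = math.sqrt(cell_area_km2) * 1000.0
    minx, miny, maxx, maxy = aoi.polygon.bounds
    ncols = max(1, math.ceil((maxx - minx) / side))
    nrows = max(1, math.ceil((maxy - miny) / side))
    cells: list[GridCell] = []
    prepared = shapely.prepared.prep(aoi.polygon)
    for row in range(nrows):
        for col in range(ncols):
            x0 = minx + col * side
            y0 = miny + row * side
            poly = box(x0, y0, x0 + side, y0 + side)
            if prepared.intersects(poly):
                cells.append(
                    GridCell(
                        id=row * ncols + col,
                        row=row,
                        col=col,
                        polygon=poly,
                        centroid=(x0 + side / 2.0, y0 + side / 2.0),
                    )
                )
    return Grid(
        cell_area_km2=cell_area_km2,
        origin=(minx, miny),
        side_m=side,
        nrows=nrows,
        ncols=ncols,
        cells=cells,
    )


def points_to_cell_centroids(
    points: PointObservations, grid: Grid, units: str = ""
) -> tuple[CellValues, int]:
    """Sum point values into their containing cells (the "raw data").

    Returns (CellValues, number of points dropped because they fell
    outside every grid cell).
    """
    sums: dict[int, float] = {}
    dropped = 0
    for (x, y), v in zip(points.xy, points.values):
        cid = grid.locate(x, y)
        if cid is None:
            dropped += 1
            continue
        sums[cid] = sums.get(cid, 0.0) + float(v)
    if dropped:
        warnings.warn(f"{dropped} point(s) fell outside the grid and were dropped")
    series = pd.Series(sums, dtype=float).sort_index()
    return CellValues(values=series, units=units), dropped
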