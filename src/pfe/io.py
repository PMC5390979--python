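"""Readers, writers and the end-to-end pipeline.

Formats are deliberately plain: GeoJSON or WKT for geometries, CSV for
point tables, cell values, tracks and per-draw estimates, ESRI ASCII
grid for density rasters, JSON for reports, TOML for the pipeline
configuration. Every writer has a matching reader (round-trip safe).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from . import allometry, catch_model, kde, pfe_core, track_validation
from .geo_grid import (
    CellValues,
    Coastline,
    Grid,
    GridCell,
    PointObservations,
    buffer_seaward,
    build_grid,
    points_to_cell_centroids,
    project_geometry,
    select_coastal_communities,
)

log = logging.getLogger("pfe")


# ---------------------------------------------------------------- geometries

def read_coastline(path: str | Path, projected: bool = False) -> Coastline:
    """Read a coastline from GeoJSON (.geojson/.json) or WKT text."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".geojson", ".json"):
        obj = json.loads(text)
        if obj.get("type") == "FeatureCollection":
            obj = obj["features"][0]["geometry"]
        elif obj.get("type") == "Feature":
            obj = obj["geometry"]
        geom = shape(obj)
    else:
        geom = shapely.from_wkt(text.strip())
    return Coastline(geometry=geom, crs="projected" if projected else "geographic")


def write_geometry_geojson(geom, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"type": "Feature", "geometry": mapping(geom), "properties": {}}))


def write_grid_geojson(grid: Grid, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(c.polygon),
            "properties": {"cell_id": c.id, "row": c.row, "col": c.col},
        }
        for c in grid.cells
    ]
    meta = {
        "cell_area_km2": grid.cell_area_km2,
        "origin": list(grid.origin),
        "side_m": grid.side_m,
        "nrows": grid.nrows,
        "ncols": grid.ncols,
    }
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features, "pfe_grid": meta})
    )


def read_grid_geojson(path: str | Path) -> Grid:
    obj = json.loads(Path(path).read_text())
    meta = obj["pfe_grid"]
    cells = []
    for f in obj["features"]:
        poly = shape(f["geometry"])
        props = f["properties"]
        c = poly.centroid
        cells.append(
            GridCell(
                id=int(props["cell_id"]),
                row=int(props["row"]),
                col=int(props["col"]),
                polygon=poly,
                centroid=(c.x, c.y),
            )
        )
    return Grid(
        cell_area_km2=meta["cell_area_km2"],
        origin=tuple(meta["origin"]),
        side_m=meta["side_m"],
        nrows=meta["nrows"],
        ncols=meta["ncols"],
        cells=cells,
    )


# -------------------------------------------------------------- point tables

def read_points_csv(
    path: str | Path,
    projected: bool = False,
    utm_zone: int | None = None,
    source: str = "",
) -> PointObservations:
    """Read id,lon,lat,value (auto-projected) or id,x,y,value CSV.

    Rows with missing or negative values are rejected with their line
    numbers logged.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if projected or ("x" in cols and "y" in cols):
        x = df[cols["x"]].astype(float)
        y = df[cols["y"]].astype(float)
    elif "lon" in cols and "lat" in cols:
        from .projection import geographic_to_utm, utm_zone_from_lon

        lon = df[cols["lon"]].astype(float)
        lat = df[cols["lat"]].astype(float)
        if utm_zone is None:
            utm_zone = utm_zone_from_lon(float(lon.mean()))
        x, y = geographic_to_utm(lon.to_numpy(), lat.to_numpy(), utm_zone)
        x, y = pd.Series(x), pd.Series(y)
    else:
        raise ValueError(f"{path}: need lon/lat or x/y columns")
    if "value" not in cols:
        raise ValueError(f"{path}: missing 'value' column")
    value = pd.to_numeric(df[cols["value"]], errors="coerce")
    table = pd.DataFrame({"x": np.asarray(x), "y": np.asarray(y), "value": value})
    bad = table.index[table.isna().any(axis=1) | (table["value"] < 0)]
    if len(bad):
        for i in bad:
            log.warning("%s: row %d rejected (malformed or negative)", path, i + 2)
        table = table.drop(index=bad)
    if table.empty:
        raise ValueError(f"{path}: no valid rows")
    return PointObservations(table.reset_index(drop=True), source=source or str(path))


def write_points_csv(points: PointObservations, path: str | Path) -> None:
    points.table.to_csv(path, index=False)


def read_cell_values(path: str | Path, units: str = "") -> CellValues:
    df = pd.read_csv(path)
    if not {"cell_id", "value"} <= set(df.columns):
        raise ValueError(f"{path}: need cell_id,value columns")
    if df.empty:
        raise ValueError(f"{path}: empty table")
    s = pd.Series(
        df["value"].to_numpy(dtype=float), index=df["cell_id"].to_numpy(dtype=int)
    ).sort_index()
    return CellValues(values=s, units=units)


def write_cell_values(cv: CellValues, path: str | Path) -> None:
    pd.DataFrame({"cell_id": cv.values.index, "value": cv.values.to_numpy()}).to_csv(
        path, index=False
    )


# ------------------------------------------------------------------- rasters

def write_ascii_grid(raster: kde.DensityRaster, path: str | Path) -> None:
    """ESRI ASCII grid; rows written north to south per the format."""
    nrows, ncols = raster.matrix.shape
    res_m = raster.resolution_km * 1000.0
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {raster.origin[0]:.6f}\nyllcorner {raster.origin[1]:.6f}\n"
        f"cellsize {res_m:.6f}\nNODATA_value -9999\n"
    )
    body = "\n".join(
        " ".join(f"{v:.8g}" for v in row) for row in raster.matrix[::-1]
    )
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> kde.DensityRaster:
    lines = Path(path).read_text().splitlines()
    hdr = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        k, v = lines[i].split()
        hdr[k.lower()] = float(v)
        i += 1
    matrix = np.array([[float(v) for v in ln.split()] for ln in lines[i:] if ln.strip()])
    return kde.DensityRaster(
        origin=(hdr["xllcorner"], hdr["yllcorner"]),
        resolution_km=hdr["cellsize"] / 1000.0,
        matrix=matrix[::-1],
        n_points=0,
    )


# -------------------------------------------------------------------- tracks

def read_tracks_csv(path: str | Path, projected: bool = True) -> list[track_validation.Track]:
    """CSV of vessel_id,timestamp,x,y (or lon,lat); timestamp ISO-8601 or seconds."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "x" in cols and "y" in cols:
        df["_x"], df["_y"] = df[cols["x"]], df[cols["y"]]
    elif "lon" in cols and "lat" in cols:
        from .projection import geographic_to_utm, utm_zone_from_lon

        zone = utm_zone_from_lon(float(df[cols["lon"]].mean()))
        x, y = geographic_to_utm(
            df[cols["lon"]].to_numpy(), df[cols["lat"]].to_numpy(), zone
        )
        df["_x"], df["_y"] = x, y
    else:
        raise ValueError(f"{path}: need x/y or lon/lat columns")
    ts = df[cols["timestamp"]]
    if ts.dtype == object:
        t = pd.to_datetime(ts).astype("int64") / 1e9
    else:
        t = ts.astype(float)
    df["_t"] = t
    tracks = []
    for vid, g in df.groupby(cols["vessel_id"]):
        g = g.sort_values("_t")
        tracks.append(
            track_validation.Track(
                vessel_id=str(vid),
                times=g["_t"].to_numpy(),
                xy=g[["_x", "_y"]].to_numpy(),
            )
        )
    return tracks


def write_tracks_csv(tracks: list[track_validation.Track], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        for t, (x, y) in zip(tr.times, tr.xy):
            rows.append({"vessel_id": tr.vessel_id, "timestamp": t, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)


# -------------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    coastline: str | None = None
    communities: str | None = None
    boats: str | None = None
    landings: str | None = None
    tracks: str | None = None
    out_dir: str = "pfe_out"
    projected: bool = True
    seaward_buffer_km: float = 75.0
    inland_buffer_km: float = 5.0
    cell_area_km2: float = 500.0
    kde_h_km: float = 75.0
    kde_res_km: float = 1.0
    kde_mode: str = "mass_conserving"
    through_origin: bool = True
    offset: float = 1.0
    fixed_m: float | None = None
    n_draws: int = 500
    draw_size: int = 250
    seed: int = 0
    speed_max: float = 1.0
    min_points: int = 3
    observed_fleet: float | None = None
    _user_set: set = field(default_factory=set, repr=False)

    def __post_init__(self) -> None:
        for name in (
            "seaward_buffer_km", "inland_buffer_km", "cell_area_km2",
            "kde_h_km", "kde_res_km", "n_draws", "draw_size", "speed_max",
            "min_points",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        data = tomllib.loads(Path(path).read_text())
        cfg = cls(**data)
        cfg._user_set = set(data)
        return cfg

    def log_defaults(self) -> None:
        """Audit trail: every default the user did not override."""
        for f in dataclasses.fields(self):
            if f.name.startswith("_") or f.name in self._user_set:
                continue
            log.info("config default: %s = %r", f.name, getattr(self, f.name))


# ------------------------------------------------------------------ pipeline

def run_pipeline(cfg: PipelineConfig) -> dict:
    """Grid → KDE → allometry → PFE → catch fit → capacity (→ validation).

    Writes intermediate artifacts and a summary JSON to ``cfg.out_dir``;
    idempotent for a fixed seed. Any stage failure aborts with a
    stage-tagged error.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.log_defaults()
    summary: dict = {"seed": cfg.seed}

    def stage(name):
        log.info("stage: %s", name)
        return name

    try:
        s = stage("grid")
        coast = read_coastline(cfg.coastline, projected=cfg.projected)
        if coast.crs != "projected":
            geom, zone = project_geometry(coast.geometry)
            coast = Coastline(geometry=geom, crs="projected", utm_zone=zone)
            summary["utm_zone"] = zone
        aoi = buffer_seaward(coast, cfg.seaward_buffer_km)
        grid = build_grid(aoi, cfg.cell_area_km2)
        write_grid_geojson(grid, out / "grid.geojson")
        write_geometry_geojson(aoi.polygon, out / "aoi.geojson")
        summary["n_cells"] = len(grid.cells)
        summary["area_km2"] = len(grid.cells) * cfg.cell_area_km2

        s = stage("kde")
        kcfg = kde.KdeConfig(cfg.kde_h_km, cfg.kde_res_km, cfg.kde_mode)
        extent = aoi.polygon.bounds
        layers: dict[str, CellValues] = {}
        sources = {"population": cfg.communities, "boats": cfg.boats, "catch": cfg.landings}
        for name, p in sources.items():
            if p is None:
                continue
            pts = read_points_csv(p, projected=cfg.projected)
            if name == "population":
                pts = select_coastal_communities(pts, coast, cfg.inland_buffer_km)
            raw, _ = points_to_cell_centroids(pts, grid, units=name)
            write_cell_values(raw, out / f"{name}_raw.csv")
            raster = kde.density_surface(pts, kcfg, extent)
            write_ascii_grid(raster, out / f"{name}_kde.asc")
            layers[name] = kde.aggregate_mean(
                raster, grid, units=name, cell_totals=True
            )
            write_cell_values(layers[name], out / f"{name}_cells.csv")

        s = stage("allometry")
        if "boats" not in layers or "population" not in layers:
            raise ValueError("need both boats and communities inputs")
        fit = allometry.fit_power_law(
            layers["boats"], layers["population"],
            through_origin=cfg.through_origin, offset=cfg.offset,
        )
        m = cfg.fixed_m if cfg.fixed_m is not None else fit.m
        summary["allometry"] = {
            "m": fit.m, "se_m": fit.se_m, "r2": fit.r2, "n": fit.n,
            "m_used": m,
        }

        s = stage("pfe")
        surface = pfe_core.compute_pfe(layers["boats"], layers["population"], m)
        write_cell_values(surface.cells, out / "pfe_cells.csv")
        summary["pfe"] = {
            "total": float(surface.values.sum()),
            "max": float(surface.values.max()),
        }

        if "catch" in layers:
            s = stage("catch_fit")
            cfit = catch_model.fit_catch_model(
                surface.cells, layers["catch"],
                n_draws=cfg.n_draws, draw_size=cfg.draw_size, seed=cfg.seed,
            )
            pd.DataFrame(
                [{"K": d["K"], "b": d["b"]} for d in cfit.per_draw]
            ).to_csv(out / "per_draw.csv", index=False)
            summary["catch_fit"] = {
                "K": cfit.K, "b": cfit.b, "ci_K": list(cfit.ci_K),
                "ci_b": list(cfit.ci_b), "r2": cfit.r2,
                "n_cells_used": cfit.n_cells_used,
            }

            s = stage("capacity")
            observed = cfg.observed_fleet
            if observed is None:
                boats_pts = read_points_csv(cfg.boats, projected=cfg.projected)
                observed = float(boats_pts.values.sum())
            report = catch_model.capacity_report(
                cfit, n_cells=len(grid.cells),
                cell_area_km2=cfg.cell_area_km2, observed_fleet=observed,
            )
            summary["capacity"] = dataclasses.asdict(report)

        if cfg.tracks is not None:
            s = stage("validation")
            tracks = read_tracks_csv(cfg.tracks, projected=cfg.projected)
            events = []
            for tr in tracks:
                events.extend(
                    track_validation.detect_fishing_events(
                        tr, cfg.speed_max, cfg.min_points
                    )
                )
            freq, _ = track_validation.events_per_cell(events, grid)
            vres = track_validation.validate_pfe(surface, freq)
            summary["validation"] = {
                "r2": vres.r2, "p": vres.p, "pearson_rho": vres.pearson_rho,
                "df": vres.df, "n_events": len(events),
                "outlier_cells": [int(c) for c in vres.outlier_cells],
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{s}' failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
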