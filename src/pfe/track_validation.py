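"""GPS-track fishing-event detection and PFE validation.

Hand-held GPS tracks from fishing vessels let the effort surface be
checked against behaviour on the water: gear deployment and retrieval
show up as sustained low-speed runs. Events are detected as maximal runs
of consecutive low-speed segments, counted per analysis cell, and the
per-cell fishing frequency is regressed on PFE (OLS with intercept,
plus a Pearson correlation); cells outside the fit's 95% prediction
interval are flagged as outliers.

The speed threshold and minimum run length are heuristics the tracks
themselves must justify — defaults are 1 m/s (~2 knots) and 3 points —
and gear-specific presets simply bundle different values of the same
two knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .geo_grid import CellValues, Grid
from .pfe_core import PfeSurface

# speed_max (m/s), min_points — gear profiles as presets, not code paths
GEAR_PRESETS = {
    "default": (1.0, 3),
    "gillnet": (0.8, 3),
    "trawl": (1.5, 4),
}


@dataclass
class Track:
    vessel_id: str
    times: np.ndarray  # seconds, strictly increasing
    xy: np.ndarray  # (n, 2) projected m

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if len(self.times) < 2:
            raise ValueError("a track needs at least 2 points")
        if len(self.times) != len(self.xy):
            raise ValueError("times and positions must align")
        if (np.diff(self.times) < 0).any():
            raise ValueError("timestamps must be increasing")


@dataclass
class FishingEvent:
    vessel_id: str
    start: int  # index of first point in the low-speed run
    end: int  # index of last point (inclusive)
    location: tuple[float, float]
    cell_id: int | None = None


@dataclass
class ValidationResult:
    r2: float
    F: float
    p: float
    pearson_rho: float
    df: int
    n: int
    slope: float
    intercept: float
    outlier_cells: list = field(default_factory=list)


def compute_speeds(track: Track) -> np.ndarray:
    """Per-segment speed (m/s) between consecutive points."""
    dt = np.diff(track.times)
    if (dt == 0).any():
        raise ValueError("duplicate timestamps in track")
    d = np.linalg.norm(np.diff(track.xy, axis=0), axis=1)
    return d / dt


def detect_fishing_events(
    track: Track, speed_max: float = 1.0, min_points: int = 3
) -> list[FishingEvent]:
    """Maximal low-speed runs of ≥ min_points GPS points become events.

    A run of k consecutive segments with speed ≤ speed_max spans k+1
    points; it qualifies when k+1 ≥ min_points. The event location is
    the midpoint of the run's bounding segment (first to last point).
    """
    if speed_max <= 0:
        raise ValueError("speed_max must be positive")
    if min_points < 2:
        raise ValueError("min_points must be at least 2")
    speeds = compute_speeds(track)
    slow = speeds <= speed_max
    events: list[FishingEvent] = []
    i = 0
    n_seg = len(slow)
    while i < n_seg:
        if not slow[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_seg and slow[j + 1]:
            j += 1
        # run covers points i .. j+1
        if (j + 2 - i) >= min_points:
            p0, p1 = track.xy[i], track.xy[j + 1]
            mid = ((p0[0] + p1[0]) / 2.0, (p0[1] + p1[1]) / 2.0)
            events.append(
                FishingEvent(vessel_id=track.vessel_id, start=i, end=j + 1, location=mid)
            )
        i = j + 1
    return events


def events_per_cell(
    events: list[FishingEvent], grid: Grid
) -> tuple[CellValues, int]:
    """Count fishing events per grid cell; events outside the grid are
    dropped (with a warning via the returned count)."""
    counts: dict[int, int] = {}
    dropped = 0
    for ev in events:
        cid = grid.locate(*ev.location)
        ev.cell_id = cid
        if cid is None:
            dropped += 1
            continue
        counts[cid] = counts.get(cid, 0) + 1
    series = pd.Series(counts, dtype=float).sort_index()
    return CellValues(values=series, units="fishing events"), dropped


def validate_pfe(
    pfe: PfeSurface | CellValues, frequency: CellValues, alpha: float = 0.05
) -> ValidationResult:
    """OLS of observed fishing frequency on PFE, with Pearson correlation.

    Cells whose observed frequency falls outside the fit's
    (1 − alpha) prediction interval are reported as outliers.
    """
    cells = pfe.cells if isinstance(pfe, PfeSurface) else pfe
    x, y, ids = cells.aligned_with(frequency)
    if len(x) < 3:
        raise ValueError("need at least 3 shared cells")
    if np.ptp(x) == 0:
        raise ValueError("constant PFE: regression undefined")

    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    rho, _ = stats.pearsonr(x, y)

    pred = res.get_prediction(X)
    lo, hi = pred.conf_int(obs=True, alpha=alpha).T
    outliers = [ids[i] for i in np.nonzero((y < lo) | (y > hi))[0]]

    return ValidationResult(
        r2=float(res.rsquared),
        F=float(res.fvalue),
        p=float(res.f_pvalue),
        pearson_rho=float(rho),
        df=int(res.df_resid),
        n=len(x),
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        outlier_cells=list(outliers),
    )
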