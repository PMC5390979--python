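"""Synthetic study regions with the statistical structure the method assumes.

A scenario bundles everything needed to exercise the full pipeline
without real data: a curved coastline, coastal communities with
lognormal populations, boat counts following a noisy power law of
population, landings following the saturating catch-effort curve with
multiplicative noise, and vessel tracks with labelled low-speed fishing
events. All draws flow from one seed, so outputs are bit-reproducible.

Defaults emulate a Gulf-of-California-like region: ~150 communities
whose lognormal sizes (mu = 7, sigma = 1.5 on the natural-log scale)
span fishing camps to port cities and total around a million people,
an allometric exponent near 0.43, and catch parameters K = 2204 t per
cell per year, b = 47.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .geo_grid import CellValues, Coastline, Grid, PointObservations
from .track_validation import Track

# projected origin of the synthetic region (m); arbitrary but UTM-like
_X0, _Y0 = 400_000.0, 3_000_000.0


@dataclass
class SyntheticScenario:
    seed: int = 0
    coast_length_km: float = 1200.0
    coast_amplitude_km: float = 40.0
    coast_cycles: float = 2.0
    n_communities: int = 150
    pop_mu: float = 7.0
    pop_sigma: float = 1.5
    m_true: float = 0.43
    sigma_b: float = 0.3
    K_true: float = 2204.0
    b_true: float = 47.0
    sigma_c: float = 0.3
    n_vessels: int = 20
    events_per_vessel: int = 3
    points_per_event: int = 5
    fishing_speed: float = 0.5  # m/s
    cruise_speed: float = 6.0  # m/s
    fix_interval_s: float = 120.0

    def __post_init__(self) -> None:
        if self.n_communities < 2:
            raise ValueError("need at least 2 communities")
        for name in ("sigma_b", "sigma_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.K_true <= 0 or self.b_true <= 0:
            raise ValueError("K_true and b_true must be positive")


def _coastline_points(sc: SyntheticScenario, n: int = 400) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)
    x = _X0 + t * sc.coast_length_km * 1000.0
    y = _Y0 + sc.coast_amplitude_km * 1000.0 * np.sin(
        2.0 * np.pi * sc.coast_cycles * t
    )
    return np.column_stack([x, y])


def generate_region(
    sc: SyntheticScenario,
) -> tuple[Coastline, PointObservations, PointObservations]:
    """Coastline, communities and boat counts for one synthetic region.

    Communities sit within 5 km inland of the coastline at jittered
    uniform arc positions; population is lognormal; boats per community
    are round(population^m_true · e^ε) with ε ~ N(0, sigma_b²).
    """
    rng = np.random.default_rng(sc.seed)
    coast_xy = _coastline_points(sc)
    coastline = Coastline(geometry=LineString(coast_xy), crs="projected")

    t = np.sort(rng.uniform(0.0, 1.0, sc.n_communities))
    x = _X0 + t * sc.coast_length_km * 1000.0
    y_coast = _Y0 + sc.coast_amplitude_km * 1000.0 * np.sin(
        2.0 * np.pi * sc.coast_cycles * t
    )
    # inland (negative-y side), 0-4.5 km so the 5 km rule keeps everyone
    y = y_coast - rng.uniform(0.0, 4500.0, sc.n_communities)

    population = np.floor(rng.lognormal(sc.pop_mu, sc.pop_sigma, sc.n_communities)) + 1
    eps = rng.normal(0.0, sc.sigma_b, sc.n_communities)
    boats = np.round(population**sc.m_true * np.exp(eps))

    communities = PointObservations(
        pd.DataFrame({"x": x, "y": y, "value": population}), source="synthetic census"
    )
    boat_obs = PointObservations(
        pd.DataFrame({"x": x, "y": y, "value": boats}), source="synthetic boat survey"
    )
    return coastline, communities, boat_obs


def generate_catch(
    pfe: CellValues,
    K_true: float,
    b_true: float,
    sigma_c: float,
    seed: int,
) -> CellValues:
    """Landings from the saturating curve with multiplicative noise.

    catch = K_true·e^(−b_true/pfe)·e^η, η ~ N(0, sigma_c²); cells with
    pfe = 0 land nothing.
    """
    rng = np.random.default_rng(seed)
    p = pfe.values.to_numpy()
    eta = rng.normal(0.0, sigma_c, len(p))
    with np.errstate(divide="ignore"):
        catch = np.where(
            p > 0, K_true * np.exp(-b_true / np.where(p > 0, p, 1.0)) * np.exp(eta), 0.0
        )
    return CellValues(
        values=pd.Series(catch, index=pfe.values.index), units="tonnes"
    )


def generate_tracks(
    sc: SyntheticScenario, grid: Grid
) -> tuple[list[Track], list[dict]]:
    """Vessel tracks with embedded, labelled low-speed fishing events.

    Each vessel runs port → ground → … → port: cruise legs at
    ``cruise_speed`` and ``events_per_vessel`` fishing bouts of
    ``points_per_event`` fixes at ``fishing_speed``. Ground truth is the
    list of events with their midpoint locations and grid cells, so a
    detector with matching thresholds must recover it exactly.
    """
    rng = np.random.default_rng(sc.seed + 1)
    dt = sc.fix_interval_s
    cruise_step = sc.cruise_speed * dt
    fish_step = sc.fishing_speed * dt
    centroids = grid.centroids()
    lo = centroids.min(axis=0)
    hi = centroids.max(axis=0)

    tracks: list[Track] = []
    truth: list[dict] = []
    for v in range(sc.n_vessels):
        port = rng.uniform(lo, hi)
        pts = [port]
        for _ in range(sc.events_per_vessel):
            # cruise leg of a few fixes toward a random heading
            heading = rng.uniform(0.0, 2.0 * np.pi)
            for _ in range(rng.integers(3, 7)):
                step = cruise_step * np.array([np.cos(heading), np.sin(heading)])
                pts.append(pts[-1] + step)
            # fishing bout: points_per_event slow fixes
            start_idx = len(pts) - 1
            f_heading = rng.uniform(0.0, 2.0 * np.pi)
            for _ in range(sc.points_per_event - 1):
                step = fish_step * np.array([np.cos(f_heading), np.sin(f_heading)])
                pts.append(pts[-1] + step)
            p0, p1 = pts[start_idx], pts[-1]
            mid = ((p0[0] + p1[0]) / 2.0, (p0[1] + p1[1]) / 2.0)
            truth.append(
                {
                    "vessel_id": f"v{v:03d}",
                    "location": mid,
                    "cell_id": grid.locate(*mid),
                }
            )
        # return leg so the last bout is bounded by fast segments
        heading = rng.uniform(0.0, 2.0 * np.pi)
        for _ in range(3):
            step = cruise_step * np.array([np.cos(heading), np.sin(heading)])
            pts.append(pts[-1] + step)
        xy = np.array(pts)
        times = np.arange(len(pts)) * dt
        tracks.append(Track(vessel_id=f"v{v:03d}", times=times, xy=xy))
    return tracks, truth
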