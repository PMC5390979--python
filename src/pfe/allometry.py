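"""Allometric scaling of boat counts with coastal population.

Boats and population are aliased predictors of fishing effort; before
combining them, their power-law relationship boats = k·population^m is
fitted on log-log axes. The through-origin form (k fixed at 1) encodes
the premise that no people means no boats; a +1 offset inside the log
transform avoids log(0) on empty cells. The fitted exponent m feeds the
effort statistic, and a slope-1 diagnostic between counted boats and
population^m confirms the two measures are interchangeable up to noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .geo_grid import CellValues


@dataclass
class AllometryFit:
    m: float
    se_m: float
    r2: float
    F: float
    df: tuple[int, int]
    p: float
    n: int
    offset: float
    through_origin: bool
    variant: str = "post_kde"
    intercept: float | None = None  # log-scale, free-intercept fits only

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("fit needs at least 2 cells")
        if self.se_m < 0:
            raise ValueError("negative standard error")


def fit_power_law(
    boats: CellValues,
    population: CellValues,
    through_origin: bool = True,
    offset: float = 1.0,
    log_base: float = 10.0,
    variant: str = "post_kde",
) -> AllometryFit:
    """OLS of log(boats+offset) on log(population+offset).

    With ``through_origin`` the intercept is fixed at 0, so the slope is
    Σxy/Σx² — the exponent m of boats = population^m. The slope is
    invariant to the log base (both axes rescale by the same factor).
    """
    b, p, _ = boats.aligned_with(population)
    usable = (b + offset > 0) & (p + offset > 0)
    b, p = b[usable], p[usable]
    if len(b) < 2:
        raise ValueError("fewer than 2 usable cells")
    if np.all(p == 0):
        raise ValueError("population is zero everywhere")

    lb = math.log(log_base)
    y = np.log(b + offset) / lb
    x = np.log(p + offset) / lb
    X = x[:, None] if through_origin else sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    slope_idx = 0 if through_origin else 1
    return AllometryFit(
        m=float(res.params[slope_idx]),
        se_m=float(res.bse[slope_idx]),
        r2=float(res.rsquared),
        F=float(res.fvalue),
        df=(int(res.df_model), int(res.df_resid)),
        p=float(res.f_pvalue),
        n=len(b),
        offset=offset,
        through_origin=through_origin,
        variant=variant,
        intercept=None if through_origin else float(res.params[0]),
    )


def predict_boats(population: float | np.ndarray, m: float) -> float | np.ndarray:
    """Population-driven boat estimate population^m (raw scale, no offset)."""
    if m < 0:
        raise ValueError("exponent must be non-negative")
    population = np.asarray(population, dtype=float)
    if (population < 0).any():
        raise ValueError("population must be non-negative")
    out = population**m
    return float(out) if out.ndim == 0 else out


def diagnose_alias(
    boats: CellValues,
    population: CellValues,
    m: float,
    slope_tolerance: float = 0.05,
) -> dict:
    """Through-origin slope and Pearson r of counted boats vs population^m.

    A slope near 1 means the two effort proxies are aliased and can be
    combined as a geometric mean; ``slope_ok`` flags departures beyond
    ``slope_tolerance``.
    """
    b, p, _ = boats.aligned_with(population)
    est = predict_boats(p, m)
    if np.ptp(b) == 0 or np.ptp(est) == 0:
        raise ValueError("degenerate (constant) inputs")
    slope = float(np.sum(b * est) / np.sum(est**2))
    r = float(np.corrcoef(b, est)[0, 1])
    return {
        "slope": slope,
        "pearson_r": r,
        "n": len(b),
        "slope_ok": abs(slope - 1.0) <= slope_tolerance,
    }
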