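"""Saturating catch-effort model and fleet-capacity diagnostics.

Landed catch saturates with effort: catch = K·e^(−b/PFE), where K is the
maximum total catch a cell can yield (tonnes per cell per year) and b a
slope parameter in PFE units. The curve rises from 0, accelerates up to
PFE = b/2 (the inflection, where diminishing returns begin) and
approaches K asymptotically.

Fitting follows a resampling protocol to blunt spatial autocorrelation:
many random draws of cells, a nonlinear least-squares fit per draw on
log10(x+1)-transformed catch (multiplicative error), final parameters
and confidence bounds as the means over draws, and a Mantel permutation
test of fit residuals against geographic distance per draw.

Capacity arithmetic extrapolates the inflection to the whole area of
influence: fleet capacity = inflection effort × number of cells, and
overcapacity compares the observed fleet against that capacity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.spatial.distance import pdist

from .geo_grid import CellValues

TRANSFORMS = ("log10_plus1", "ln")


@dataclass
class CatchFit:
    K: float
    b: float
    ci_K: tuple[float, float]
    ci_b: tuple[float, float]
    per_draw: list[dict] = field(default_factory=list)
    n_draws: int = 0
    draw_size: int = 0
    seed: int | None = None
    r2: float = float("nan")
    transform: str = "log10_plus1"
    n_cells_used: int = 0
    n_zero_pfe_excluded: int = 0
    n_draws_dropped: int = 0

    def __post_init__(self) -> None:
        if self.K <= 0 or self.b <= 0:
            raise ValueError("K and b must be positive")
        if self.ci_K[0] > self.ci_K[1] or self.ci_b[0] > self.ci_b[1]:
            raise ValueError("confidence bounds out of order")


@dataclass
class CapacityReport:
    pfe_inflection: float
    catch_at_inflection: float
    n_cells: int
    area_km2: float
    fleet_capacity: int
    observed_fleet: float
    excess_boats: float
    excess_percent: int


def predict_catch(
    pfe: float | np.ndarray, K: float, b: float
) -> float | np.ndarray:
    """Expected catch K·e^(−b/PFE); 0 at PFE = 0 (the limit), → K as PFE → ∞."""
    if K <= 0 or b <= 0:
        raise ValueError("K and b must be positive")
    pfe = np.asarray(pfe, dtype=float)
    if (pfe < 0).any():
        raise ValueError("PFE must be non-negative")
    with np.errstate(divide="ignore"):
        out = np.where(pfe > 0, K * np.exp(-b / np.where(pfe > 0, pfe, 1.0)), 0.0)
    return float(out) if out.ndim == 0 else out


def _transform(x: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log10_plus1":
        return np.log10(x + 1.0)
    return np.log(x)


def _fit_one_draw(
    pfe: np.ndarray, catch: np.ndarray, transform: str
) -> tuple[float, float, tuple[float, float], tuple[float, float]]:
    """Nonlinear LS of transformed catch on the transformed model curve."""
    y = _transform(catch, transform)

    def model(x, K, b):
        return _transform(K * np.exp(-b / x), transform)

    # linearized start: log10(catch+1) ~ a + s/pfe gives K0 = 10^a, b0 = -s·ln10
    x_inv = 1.0 / pfe
    s, a = np.polyfit(x_inv, np.log10(catch + 1.0), 1)
    K0 = max(10.0**a, 1e-6)
    b0 = max(-s * math.log(10.0), 1e-6)
    popt, pcov = optimize.curve_fit(
        model, pfe, y, p0=[K0, b0], bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        maxfev=10_000,
    )
    K, b = float(popt[0]), float(popt[1])
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    dof = max(len(pfe) - 2, 1)
    tcrit = stats.t.ppf(0.975, dof)
    ci_K = (K - tcrit * se[0], K + tcrit * se[0])
    ci_b = (b - tcrit * se[1], b + tcrit * se[1])
    return K, b, ci_K, ci_b


def fit_catch_model(
    pfe: CellValues,
    catch: CellValues,
    n_draws: int = 500,
    draw_size: int = 250,
    seed: int | None = None,
    transform: str = "log10_plus1",
    locations: np.ndarray | None = None,
    mantel_n_perm: int = 199,
) -> CatchFit:
    """Resampled nonlinear fit of the saturating catch-effort curve.

    Each of ``n_draws`` draws samples ``draw_size`` cells without
    replacement and fits the curve by least squares on the transformed
    scale. The reported K, b and 95% bounds are the means of the
    per-draw estimates and bounds. Cells with PFE = 0 (model undefined)
    are excluded up front. When per-cell ``locations`` (projected
    centroids aligned with the shared cells) are given, each draw also
    gets a Mantel test of its residuals against geographic distance.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"transform must be one of {TRANSFORMS}")
    if seed is None:
        raise ValueError("seed is required")
    p, c, ids = pfe.aligned_with(catch)
    positive = p > 0
    if transform == "ln":
        positive &= c > 0
    n_excluded = int((~positive).sum())
    if n_excluded:
        warnings.warn(f"{n_excluded} cell(s) with PFE=0 (or catch=0) excluded from fit")
    p, c = p[positive], c[positive]
    if locations is not None:
        locations = np.asarray(locations, dtype=float)[positive]
    if draw_size > len(p):
        raise ValueError(
            f"draw_size {draw_size} exceeds the {len(p)} usable cells"
        )

    rng = np.random.default_rng(seed)
    per_draw: list[dict] = []
    dropped = 0
    for _ in range(n_draws):
        idx = rng.choice(len(p), size=draw_size, replace=False)
        try:
            K_i, b_i, ciK_i, cib_i = _fit_one_draw(p[idx], c[idx], transform)
        except (RuntimeError, ValueError):
            dropped += 1
            continue
        rec = {"K": K_i, "b": b_i, "ci_K": ciK_i, "ci_b": cib_i}
        if locations is not None:
            resid = _transform(c[idx], transform) - _transform(
                predict_catch(p[idx], K_i, b_i), transform
            )
            try:
                r_m, p_m = mantel_test(
                    resid, locations[idx], n_perm=mantel_n_perm,
                    seed=int(rng.integers(2**31 - 1)),
                )
            except ValueError:
                r_m, p_m = float("nan"), float("nan")
            rec["mantel_r"] = r_m
            rec["mantel_p"] = p_m
        per_draw.append(rec)

    if dropped:
        warnings.warn(f"{dropped} non-convergent draw(s) dropped")
    if dropped > 0.1 * n_draws:
        raise RuntimeError(f"{dropped}/{n_draws} draws failed to converge")

    Ks = np.array([d["K"] for d in per_draw])
    bs = np.array([d["b"] for d in per_draw])
    K_hat, b_hat = float(Ks.mean()), float(bs.mean())
    ci_K = (
        float(np.mean([d["ci_K"][0] for d in per_draw])),
        float(np.mean([d["ci_K"][1] for d in per_draw])),
    )
    ci_b = (
        float(np.mean([d["ci_b"][0] for d in per_draw])),
        float(np.mean([d["ci_b"][1] for d in per_draw])),
    )
    pred = predict_catch(p, K_hat, b_hat)
    ss_res = float(np.sum((c - pred) ** 2))
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    return CatchFit(
        K=K_hat,
        b=b_hat,
        ci_K=ci_K,
        ci_b=ci_b,
        per_draw=per_draw,
        n_draws=n_draws,
        draw_size=draw_size,
        seed=seed,
        r2=r2,
        transform=transform,
        n_cells_used=len(p),
        n_zero_pfe_excluded=n_excluded,
        n_draws_dropped=dropped,
    )


def mantel_test(
    residuals: np.ndarray,
    locations: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel permutation test of residual dissimilarity vs distance.

    The statistic is the Pearson correlation between the condensed
    (lower-triangle) residual dissimilarity matrix |rᵢ − rⱼ| and the
    Euclidean distance matrix of the locations. Permutations shuffle the
    residual labels; the one-sided p-value for positive autocorrelation
    is (1 + #{r_perm ≥ r_obs}) / (n_perm + 1).
    """
    residuals = np.asarray(residuals, dtype=float)
    locations = np.asarray(locations, dtype=float)
    if len(residuals) < 4:
        raise ValueError("Mantel test needs at least 4 points")
    if len(residuals) != len(locations):
        raise ValueError("residuals and locations must align")
    if np.ptp(residuals) == 0:
        raise ValueError("constant residuals: correlation undefined")

    d_geo = pdist(locations)
    d_res = pdist(residuals[:, None], metric="cityblock")  # |ri - rj|
    if np.ptp(d_geo) == 0:
        raise ValueError("constant distances: correlation undefined")

    def corr(v: np.ndarray) -> float:
        return float(np.corrcoef(v, d_geo)[0, 1])

    r_obs = corr(d_res)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(residuals))
        if corr(pdist(residuals[perm, None], metric="cityblock")) >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return r_obs, p


def inflection_point(b: float) -> float:
    """PFE at which catch gains start diminishing: the root b/2 of the
    second derivative of K·e^(−b/PFE)."""
    if b <= 0:
        raise ValueError("b must be positive")
    return b / 2.0


def capacity_report(
    fit: CatchFit | tuple[float, float],
    n_cells: int,
    cell_area_km2: float = 500.0,
    observed_fleet: float = 0.0,
) -> CapacityReport:
    """Extrapolate the inflection effort to fleet capacity and overcapacity.

    ``fit`` may be a CatchFit or a bare (K, b) pair. Fleet capacity is
    the integer part (truncation) of inflection × n_cells; overcapacity
    percent is rounded to the nearest integer with capacity as the
    denominator.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    if observed_fleet < 0:
        raise ValueError("observed fleet must be non-negative")
    K, b = (fit.K, fit.b) if isinstance(fit, CatchFit) else fit
    pfe_star = inflection_point(b)
    catch_star = K * math.exp(-2.0)
    capacity = int(pfe_star * n_cells)
    if capacity == 0:
        raise ValueError("fleet capacity is zero; overcapacity percent undefined")
    excess = observed_fleet - capacity
    return CapacityReport(
        pfe_inflection=pfe_star,
        catch_at_inflection=catch_star,
        n_cells=n_cells,
        area_km2=n_cells * cell_area_km2,
        fleet_capacity=capacity,
        observed_fleet=observed_fleet,
        excess_boats=excess,
        excess_percent=int(round(100.0 * excess / capacity)),
    )
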