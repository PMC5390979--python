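# Methods

## The problem

Small-scale (artisanal) fleets are effectively untraceable once they leave
port: no VMS, patchy logbooks, landings reported only at a handful of
offices. Yet two proxies for fishing pressure are almost always available —
the size of the coastal human population and counts of boats on the water.
This package turns those two proxies into a spatially explicit **Predicted
Fishing Effort (PFE)** surface, and, where landings records exist, into a
fleet-capacity diagnosis.

## Pipeline

1. **Area of influence.** The coastline is projected to UTM (metres) and
   buffered by the mean distance fishers travel to their grounds
   (default 75 km). Everything is computed inside this polygon.
2. **Analysis grid.** Congruent square cells (default 500 km², roughly the
   fishing area available to one open skiff) tile the buffer's bounding
   box, anchored at its minimum corner; only cells intersecting the area of
   influence are kept. Cell ids are row-major, 0-based.
3. **Kernel density estimation.** Point observations (people, boats,
   tonnes) are spread with the quadratic Epanechnikov kernel
   K(u) = ¾(1 − u²), support equal to the buffer distance h, on a 1 km²
   pixel raster, then averaged per analysis cell.
4. **Allometry.** Boats scale with population as boats = k·population^m.
   The exponent is fitted by OLS on log-log axes, by default through the
   origin (no people → no boats), with a +1 offset inside the logs so
   empty cells do not produce log 0.
5. **PFE.** Per cell, PFE = sqrt(boats × population^m) — the geometric
   mean of the counted boats and the population-predicted boats. The two
   proxies are aliased (slope ≈ 1 between boats and population^m), so the
   geometric mean uses both without double-counting, and damps cells where
   one proxy is extreme. Units: boats per day per cell, adjusted by the
   local population.
6. **Catch model.** Against landed catch, effort saturates:
   catch = K·e^(−b/PFE), with K the asymptotic maximum catch per cell per
   year and b a slope parameter in PFE units. The curve inflects at
   PFE = b/2 — the onset of diminishing returns.
7. **Capacity.** Extrapolating the inflection effort over all cells gives
   the fleet size beyond which extra boats add little catch:
   capacity = int((b/2) × n_cells) (truncated). Overcapacity is the
   observed fleet minus capacity, as a count and as a percentage of
   capacity (rounded to the nearest integer).
8. **Validation (optional).** GPS tracks are segmented by speed; maximal
   runs of consecutive slow fixes are fishing events; per-cell event
   frequency is regressed on PFE (OLS + Pearson correlation), with cells
   outside the 95 % prediction interval flagged.

## Kernel normalization

The quadratic kernel admits two per-point scalings, selected by
`KdeConfig.mode`:

- `mass_conserving` (default): c(r) = (2/(πh²))(1 − r²/h²), the proper 2-D
  Epanechnikov density, which integrates to 1 over the disc of radius h.
  Each point of value u deposits exactly u onto the surface (tested to
  < 1 % discretization error for points ≥ h from the raster edge). Total
  boats and people are conserved — a checkable contract.
- `paper_literal`: c(r) = (0.75/h)(1 − r²/h²), the 1-D normalization some
  GIS workflows apply. The two surfaces are exactly proportional
  (ratio (2/(πh²))/(0.75/h)), so any statistic invariant to a global
  rescaling — the log-log slope, PFE ranks, the catch-model r² — is
  unaffected by the choice; absolute cell totals are not, which is why
  conservation is the default.

Because the points carry totals, not sample frequencies, the conventional
1/n factor of probability-density KDE is dropped; the surface keeps the
input's units per km². No edge correction is applied at the area-of-
influence boundary; mass falling outside is visible as the difference
between `DensityRaster.total_mass()` and the input total.

## Fitting the catch model

The data are log10(x+1) transformed (approximate normality, homogenized
variances), and the fit minimizes

    Σ [ log10(catch_i + 1) − log10(K·e^(−b/PFE_i) + 1) ]²

by nonlinear least squares (scipy `curve_fit`), initialized from the OLS
of log10(catch+1) on 1/PFE. Fitting on the log scale is the
multiplicative-error form: residuals are relative, not absolute, which
matches landings data whose spread grows with the mean. Keeping the +1
inside the model term (rather than linearizing it away) makes the
estimator exact on noiseless data. A natural-log, no-offset mode
(`transform="ln"`) is available; it requires positive catch.

To blunt spatial autocorrelation the fit is replicated over random draws
(default 500 draws of 250 cells each, without replacement within a draw);
the reported K, b and 95 % bounds are the means of the per-draw estimates
and per-draw t-based bounds. Cells with PFE = 0 are excluded (the model is
undefined there); their count is logged. Draws that fail to converge are
dropped, and more than 10 % failures abort the fit. A Mantel permutation
test (one-sided for positive autocorrelation, Euclidean distances on
projected centroids, p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1)) can be run
per draw when cell locations are supplied.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| seaward buffer | 75 | km | mean trip distance to fishing grounds |
| inland buffer | 5 | km | strip containing the fishing-linked populace |
| cell area | 500 | km² | fishing area per vessel; sets n_cells |
| KDE bandwidth h | 75 | km | same travel scale as the buffer |
| KDE resolution | 1 | km | pixel size before cell aggregation |
| allometry offset | +1 | — | avoids log 0 in empty cells |
| draws × draw size | 500 × 250 | — | resampling against autocorrelation |
| speed_max | 1.0 | m/s | ≈ 2 knots; gear-handling speed |
| min_points | 3 | GPS fixes | shortest run that counts as fishing |

`min_points` counts the GPS *points* of a low-speed run (a run of k slow
segments spans k + 1 points). The speed threshold and run length are
heuristics; gear presets (`gillnet`, `trawl`) are parameter bundles, not
separate logic.

## Numerical choices and tie-breaks

- UTM projection via the Krüger series to order n³ (round-trip error
  ≪ 1 m inside a zone); the zone is auto-derived from the geometry
  centroid, and a study area leaning far out of its zone only warns.
- Grid anchoring at the area-of-influence bounding-box minimum corner
  makes the grid a pure function of the polygon.
- A point exactly on a shared cell edge is assigned to the lower
  (row, col) cell; pixel membership in aggregation is by pixel center.
- Fleet capacity truncates rather than rounds (23.5 × 565 = 13,277.5 →
  13,277); the overcapacity percentage rounds to the nearest integer.
- Through-origin r² is the uncentered statsmodels definition, the
  standard one when no intercept is estimated.

## The +1 offset and small counts

The log offset is a zero-handling device, not part of the scaling law.
For cells with very few boats it inflates log(boats+1) noticeably
(log(1 + 1/boats) ≈ 0.43/boats in log10), which biases the through-origin
exponent upward by a small but — at n = 500, se ≈ 0.002 — detectable
amount. Consequently the exponent-recovery property is verified with
offset = 0 on data free of zeros; with zeros present the offset remains
the pragmatic default, and `predict_boats` and PFE always use raw values.

## What the synthetic generator does and does not emulate

`SyntheticScenario` builds a gently curved coastline (~1200 km), ~150
communities within 5 km of it, lognormal populations (mu = 7, sigma = 1.5
on the natural-log scale — fishing camps to port cities, around a million
people in total), boat counts following a noisy power law of population
(m_true = 0.43, σ_b = 0.3), landings from the saturating curve with
multiplicative noise (K = 2204, b = 47, σ_c = 0.3), and vessel tracks
whose fishing bouts are slow runs of known length and location. All
randomness flows from a single seed; outputs are bit-reproducible.

It does **not** emulate: coastline-blocked travel (kernels cross land),
bathymetry or habitat structure in where fishing happens, seasonal or
interannual dynamics, species composition, reporting error in landings
offices, or spatially correlated noise. Passing tests therefore show that
the estimator chain is correct and stable under the model's own
assumptions — not that those assumptions hold in any particular fishery.

## Problem sizes used in the test suite

Statistical properties are checked at sizes chosen to give stable rates:
200 replicates for the allometry-recovery and Mantel type-I-error rates,
20 replicates (50 draws × 250 cells each) for catch-parameter bias under
σ = 0.3, and 3 full-pipeline replicates (~490 cells each) for end-to-end
recovery. The whole suite runs in well under a minute.

## Known limitations

- The Epanechnikov kernel ignores land: density leaks across peninsulas
  and bays (no barrier-aware kernel, no edge correction).
- PFE has no absolute unit; it is comparable within one analysis, not
  across studies with different m or bandwidths.
- The catch model is a static, aggregate curve — not a stock assessment;
  K and b fold together productivity, accessibility and reporting.
- Fleet capacity assumes a uniform inflection effort across cells and a
  common fishing history; it overestimates capacity where stocks are
  already depleted.
- Temporal structure (seasons, trends) is out of scope; PFE is a
  time-averaged snapshot.
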