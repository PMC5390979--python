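# pfe — Predicted Fishing Effort for data-poor small-scale fisheries

Small-scale fleets — open outboard skiffs working coastal waters — are the
backbone of many fisheries, yet once they leave port they are effectively
untraceable: no vessel-monitoring systems, patchy logbooks, landings
aggregated at a few offices. `pfe` estimates *where* and *how hard* such a
fleet fishes from two proxies that are almost always obtainable: the human
population of coastal communities and counts of boats on the water.

It is aimed at fisheries scientists and managers working on coastal
regions where conventional effort data (CPUE, VMS) do not exist.

## The method

1. Buffer the coastline by the fleet's mean trip distance (default 75 km)
   to get the *area of influence*, tiled with square cells (default
   500 km²).
2. Spread population, boat and landings points over the area with a
   quadratic (Epanechnikov) kernel, K(u) = ¾(1 − u²), bandwidth h = 75 km,
   at 1 km² resolution, aggregated to cell values.
3. Fit the allometric scaling boats = population^m by through-origin
   log-log OLS (offset +1 against log 0).
4. Combine the two aliased proxies into one effort statistic per cell:

   **PFE = √(boats × population^m)**

5. Where landings exist, fit the saturating catch-effort curve

   **catch = K·e^(−b/PFE)**

   by resampled nonlinear least squares on log10(x+1)-transformed data
   (500 draws × 250 cells; Mantel tests for residual spatial
   autocorrelation), and derive capacity: the curve inflects at
   PFE = b/2, so a fleet larger than (b/2) × n_cells is past the point of
   diminishing returns.
6. Optionally validate PFE against fishing events detected in GPS vessel
   tracks as sustained low-speed runs.

## Worked example

With the Gulf of California catch-model parameters (K = 2204 t per
500 km² per year, b = 47.0, 565 analysis cells, 17,839 boats observed):

```python
from pfe import capacity_report, inflection_point, predict_catch

star = inflection_point(47.0)
print(f"inflection effort : {star} boats per 500 km2")
print(f"catch at inflection: {predict_catch(star, 2204.0, 47.0):.2f} t per cell per yr")
r = capacity_report((2204.0, 47.0), n_cells=565, cell_area_km2=500.0,
                    observed_fleet=17839)
print(f"area of influence  : {r.area_km2:,.0f} km2")
print(f"fleet capacity     : {r.fleet_capacity:,} boats")
print(f"overcapacity       : {r.excess_boats:,.0f} boats ({r.excess_percent}%)")
```

prints

```
inflection effort : 23.5 boats per 500 km2
catch at inflection: 298.28 t per cell per yr
area of influence  : 282,500 km2
fleet capacity     : 13,277 boats
overcapacity       : 4,562 boats (34%)
```

Read: catch gains per extra boat start shrinking once effort passes 23.5
boats per cell (where a cell yields ~298 t/yr); scaled to the whole fished
area that is a capacity of 13,277 boats, so the observed fleet exceeds the
diminishing-returns point by 4,562 boats (34 %).

The full pipeline runs end-to-end on synthetic data:

```sh
pfe simulate --seed 11 --out sim/           # coastline, census, boats, landings, tracks
pfe run --config config.toml                # grid -> KDE -> allometry -> PFE -> catch fit -> capacity
```

where `config.toml` points at the files in `sim/` (see
`pfe.io.PipelineConfig` for all keys). Each stage is also its own
subcommand: `pfe grid`, `pfe kde`, `pfe allometry`, `pfe compute`,
`pfe fit-catch`, `pfe capacity`, `pfe validate`.

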