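# pestcast

Coupled mechanistic + correlative species distribution modelling for
host-limited forest pests.

Bark beetles such as the cypress bark beetle attack a single host genus
(*Cupressus*), so the pest's possible range is the intersection of two
things: where the climate suits the **pest**, and where the **host** can
persist at all. `pestcast` implements that two-model workflow end to end:

1. **Mechanistic host model** (CLIMEX-family ecoclimatic index). For each
   grid cell and week the engine computes a Temperature Index TI(t) and a
   Moisture Index MI(m), both trapezoidal responses — zero below a lower
   threshold (DV0, SM0), one across an optimum range ([DV1, DV2],
   [SM1, SM2]), zero above an upper threshold (DV3, SM3) — where *m* is a
   weekly soil-moisture bucket driven by rain and a temperature-proxy
   evapotranspiration. Cold/heat/dry/wet stresses accumulate weekly at
   fixed rates beyond their thresholds and are capped at 100. The annual
   **Ecoclimatic Index** per cell is

   ```
   EI = GIA · Π_x (1 − S_x/100),   GIA = 100 · mean_w( TI_w · MI_w )
   ```

   so EI ∈ [0, 100] and any saturated stress makes a cell unsuitable.
   The default parameter set is the fitted host (*Cupressus*)
   parameterization (DV0 = −15 °C, DV1 = 13.6 °C, DV2 = 20.4 °C,
   DV3 = 45 °C, SM0 = 0.05 … SM3 = 1.5, plus the four stress
   threshold/rate pairs).

2. **Genetic-algorithm calibration** fits engine thresholds to occurrence
   records by maximizing agreement between the EI surface and the records
   (a scale-free intensity log-likelihood, or a simpler coverage-minus-area
   score), with tournament selection, uniform crossover, Gaussian mutation,
   ordering repair, elitism, and a Nelder–Mead polish.

3. **Correlative pest model**: GBIF-style records are deduplicated,
   spatially rarefied, and complemented with pseudo-absences; the 19
   standard bioclimatic layers are screened (pairwise Pearson |r| > 0.8,
   then L1-logistic selection) and a random forest is evaluated by AUC,
   True Skill Statistic and Cohen's kappa over 10 stratified 70/30 splits.

4. **Mapping**: the pest probability raster is restricted to host-suitable
   cells (EI > 0 mask), classified into five suitability levels by exact
   Jenks natural breaks, and summarized as per-region suitable areas
   (spherical cell-area weighting) with percent changes between climate
   epochs.

A seed-deterministic synthetic-world generator (latitudinal temperature
gradient, hemisphere-phased seasons, equator/storm-track precipitation with
a winter-wet cycle) drives every stage without any data download.

## Worked example

```python
import numpy as np
import pestcast as pc

spec = pc.SyntheticWorldSpec()          # 90 x 180 cells, 2 degree grid, seed 0
climate = pc.make_synthetic_climate(spec)
ei = pc.run_grid(climate, pc.ClimexParameters())
print(f"suitable cells (EI > 0): {(ei.ei > 0).mean():.1%}")
print(f"max EI: {np.nanmax(ei.ei):.1f}")

future = pc.run_grid(pc.warm_future(climate, delta_t=2.0), pc.ClimexParameters())
breaks = pc.jenks_breaks(ei.ei[ei.ei > 0], k=5, max_n=2000)
cur = pc.classify(ei.ei, breaks, ei.lat_axis, ei.lon_axis)
fut = pc.classify(future.ei, breaks, ei.lat_axis, ei.lon_axis)
masks = pc.synthetic.regions_as_dict(pc.make_region_masks(spec, 6))
report = pc.area_report(cur, fut, masks)
print(report.totals.round(2).to_string(index=False))
```

prints

```
suitable cells (EI > 0): 47.4%
max EI: 63.1
  region  suitable_current  suitable_future  percent_change
region_1           5097.29          5307.99            4.13
region_2           5034.57          5250.43            4.29
region_3           5065.44          5255.77            3.76
region_4           5056.73          5263.15            4.08
region_5           5138.57          5312.78            3.39
region_6           5081.10          5243.65            3.20
  global          30473.70         31633.77            3.81
```

The host occupies a subtropical belt in each hemisphere (47% of cells,
peak EI 63); warming the same world by 2 °C grows every synthetic
continent's suitable area (units 10⁴ km²) by 3–4% as the belts shift
poleward.

The same pipeline is scriptable from the shell:

```bash
pestcast synth world --nlat 90 --nlon 180 --out clim.csv
pestcast engine --climate clim.csv --out ei.csv
pestcast classify --raster ei.csv --out classes.csv
```

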