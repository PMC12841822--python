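# Methods

This note documents the models implemented in `pestcast`, the choices made
where the underlying methods are conventionally under-specified, and what
the synthetic-data experiments do and do not demonstrate.

## The ecoclimatic engine

The engine is a CLIMEX-family annual suitability model. All state is
per grid cell; the year is 52 weeks of 365/52 days (no leap years). Week
*w* spans days [w·365/52, (w+1)·365/52).

**Weekly drivers.** Monthly temperature and humidity are state variables:
they are interpolated piecewise-linearly between mid-month anchor values,
periodically across the year boundary, and evaluated at week midpoints.
Monthly precipitation is a flux: each month's total is divided across the
weeks that overlap it in proportion to overlapping days, which conserves
the annual total exactly (the test suite asserts conservation to 0.5%).
The engine's single humidity input is the mean of the 09:00 and 15:00
relative humidities; the default engine does not otherwise consume
humidity (moisture enters through the rain-driven bucket), so this choice
only affects downstream consumers of the weekly series.

**Growth.** The weekly Temperature Index is a trapezoid over
(DV0, DV1, DV2, DV3) evaluated at the weekly mean temperature
(tmin+tmax)/2; the Moisture Index is a trapezoid over (SM0, SM1, SM2, SM3)
evaluated on the bucket state. The trapezoid is the standard shape in this
model family; sources typically publish only the four thresholds, so no
nonlinear segment near the upper threshold is modelled. The annual growth
index is GIA = 100·mean(TI·MI).

**Soil moisture.** A weekly bucket
`m ← clamp(m + (rain − Epot)/C, 0, 2)` with potential evapotranspiration
proxied as Epot = max(0, 0.8·T) mm/week and capacity C = 100 mm. These
hydrological constants are fixed engine constants (`EngineConstants`), not
fitted quantities; they were chosen so that realistic mid-latitude rainfall
makes the bucket traverse the published SM thresholds (0.05–1.5). There is
no drainage term: surplus beyond m = 2 is shed. The annual cycle is spun up
from m = 1.0 until the week-1 state changes by < 1e−6 between cycles (at
most 10 cycles), then one recorded pass is taken. Whenever the trajectory
touches a clamp during the year — the typical case — the recorded cycle is
independent of the initial state; in the measure-zero case of an exactly
balanced, clamp-free budget the cycle legitimately depends on the start,
which is why the spin-up test uses a clamping seasonal cell.

**Stress.** Weekly increments |rate| × positive exceedance of the stress
threshold: (TTCS − T) for cold, (T − TTHS) for heat, (SMDS − m) for dry,
(m − SMWS) for wet. Published cold and dry rates carry a negative sign by
convention and are used as magnitudes. The annual sum is capped at 1 and
scaled to 100. The four stresses combine multiplicatively in
EI = GIA·Π(1 − S/100), so any saturated stress forces EI = 0, and EI is
monotone in each stress and in GIA.

**Parameters.** The default `ClimexParameters` is the host (*Cupressus*)
parameterization: DV0 = −15 °C (winter survival limit), optimum
13.6–20.4 °C (annual mean minima/maxima of two reference cypress stands),
DV3 = TTHS = 45 °C (hot edge of the native range), SM0 = SMDS = 0.05
(permanent wilting point), SM1/SM2/SM3 = 0.5/0.9/1.5 (Mediterranean /
temperate / semi-arid habitat templates), THCS = −0.125, THHS = 0.015,
HDS = −0.005, HWS = 0.012 week⁻¹.

## Calibration

Two agreement objectives are implemented.

* `fitness`: coverage − w·area, where coverage is the fraction of
  occurrence cells with EI > 0 and area is the area-weighted fraction of
  the world with EI > 0 (w = 0.3 by default). This score sees only the
  *support* of the EI surface. The optimum-range thresholds DV1/DV2 move
  EI's magnitude but never its support, so they are unidentifiable from
  this objective; it is retained as the simple, transparent score.
* `occurrence_loglik` (the `fit_parameters` default): the log-likelihood
  of records drawn with probability proportional to EI,
  `mean_occ log(EI + ε) − log(mean_cells EI + ε)` with ε = 1e−3 on the
  0–100 EI scale. It is scale-free, rewards high EI where records are
  dense, and its normalizer penalizes suitability predicted far from any
  record (overprediction) with no extra weight. On the default synthetic
  world the infinite-sample version of this score is maximized exactly at
  the generating DV1/DV2.

The search is a real-coded GA — tournament selection of size 2, uniform
crossover (rate 0.7), per-gene Gaussian mutation (rate 0.25, sd = 10% of
the bound width) clipped to bounds, ordering repair (each threshold
quadruple is sorted), and elitism (the incumbent replaces the worst child
when no child improves), followed by Nelder–Mead refinement from three
deterministic starts (the GA incumbent, the template parameter vector, and
the bounds midpoint). 75% of records train the objective; the held-out 25%
report an independent coverage.

By default only the growth thresholds are searched (`DEFAULT_BOUNDS`
frees DV0–DV3 and SM0–SM3); stress rates stay at their literature values.
The threshold-recovery experiment frees the four temperature thresholds and
keeps the moisture thresholds at their template values, mirroring the
fitting protocol of the host parameterization. That restriction matters:
with all eight growth thresholds free, the TI×MI product has a
compensation ridge (a flattened moisture response can absorb a shifted
temperature plateau), and the recovery experiment would be testing the
identifiability of an over-parameterized fit rather than the calibrator.
The experiment uses 6,625 sampled records — the size of the retained host
occurrence dataset — because the likelihood around the optimum is shallow
and smaller samples leave threshold estimates with multi-degree spread.

## Occurrence handling

Deduplication rounds coordinates to 1e−4° and keeps the first record of
each (lon, lat, label) triple, preserving input order. Rarefaction is
greedy in input order: a record is kept iff it lies at least the minimum
great-circle distance (haversine, R = 6,371 km) from every previously kept
record; the result is idempotent but order-dependent, which is documented
behaviour. Pseudo-absences are drawn uniformly over valid cells (uniform
cell, uniform within-cell position), rejected inside a 50 km buffer around
any presence (configurable), with a 10,000·n draw budget.

## Correlative model

Screening is two-stage. The Pearson filter walks bio1…bio19 in order and
drops a layer iff |r| > 0.8 against any already-retained layer, so the
earlier layer of a correlated pair wins deterministically; constant layers
are dropped with a warning. The LASSO stage fits L1-penalized logistic
regression on standardized predictors, choosing the penalty over a log grid
by 5-fold stratified CV log-loss with the one-standard-error rule; if it
zeroes out everything the pipeline falls back to the Pearson set with a
warning.

"10-fold cross-validation" combined with a 70% training share is
implemented as 10 stratified random 70/30 splits (a literal 10-fold
partition cannot have a 70/30 ratio). Per split the forest (500 trees by
default) is evaluated on the held-out 30%: AUC as the rank statistic, TSS
= sensitivity + specificity − 1 at the threshold maximizing TSS (lowest
threshold on ties), and Cohen's kappa at that same threshold. TSS here is
the True Skill Statistic — the [−1, 1] range makes that reading
unambiguous. Variable importance is permutation importance (AUC scoring,
5 repeats) on held-out data, accumulated over splits and normalized to
percent; permutation importance is preferred over Gini because the layers
are strongly correlated.

Note one small-sample property of the max-TSS threshold rule: under a
label permutation with only ~60 held-out records, its null expectation is
about +0.12 purely from threshold selection. The null diagnostic therefore
runs at a 10× larger sample, where the statistic actually measures
spurious skill rather than selection bias.

## Mapping and areas

Jenks natural breaks are computed exactly by dynamic programming over the
sorted values (O(k·n²)); ties break toward the lower break values, and each
break is the minimum of its upper class so that half-open classification
[bᵢ, bᵢ₊₁) reproduces the optimal partition. Inputs larger than `max_n`
are subsampled evenly across the sorted order before the exact
optimization, as map classifiers conventionally do. The host mask is
1 iff EI > 0 (strict); masked cells have their pest probability set to 0,
so they classify as "unsuitable" rather than disappearing as nodata, and
every land cell keeps a class. Cell areas use the spherical band formula
A = R²·Δλ·(sin φ_top − sin φ_bottom), which sums to 4πR² over a global
grid. "Suitable area" means all classes above "unsuitable" (`min_class=1`,
configurable, since the boundary between reporting conventions is
genuinely ambiguous). Change maps and cross-epoch area comparisons reuse
the current-epoch breaks for both epochs so ordinal differences are
comparable; per-epoch breaks remain available.

## The synthetic world

The generator emulates the gross structure of gridded global climatology:
annual mean temperature 27 − 0.55·|lat| °C, seasonal half-amplitude
15·|lat|/90 °C phased July/January by hemisphere, diurnal half-range 5 °C;
annual precipitation with an equatorial peak (1,600 mm, width 18°),
mid-latitude storm-track peaks (700 mm at 45°, width 12°) and a 120 mm
background, distributed over months with a winter-wet cycle of relative
amplitude 0.8. Under the default engine parameters this yields subtropical
suitable belts in both hemispheres with peak EI ≈ 60 — the qualitative
pattern the host model is meant to produce — because the bucket crosses
the SM1–SM2 optimum during the dry-down and the mean temperature sits in
the DV1–DV2 range there.

Cell-level variability is deliberately structured for identifiability:
Gaussian noise on the annual mean (1 °C), on the seasonal amplitude
(1.5 °C, "continentality"), and on the diurnal half-range (1.5 °C), plus
multiplicative lognormal noise on the annual precipitation total (10%) and
independently per month (25%). Without the amplitude and diurnal noise,
the annual temperature range (bio7) would be an exact function of latitude
(cell noise on the annual mean cancels in bio5 − bio6) and no experiment
could attribute signal to it; without per-month precipitation noise the
coldest-quarter precipitation (bio19) would carry no variation independent
of the annual-total cluster.

What the generator does **not** model: spatial autocorrelation of the
noise, topography, land/ocean geometry, realistic circulation-driven
climate-change patterns (the "future" is a uniform warming plus a
precipitation scale factor), or observation bias in records. Passing
tests therefore demonstrate that the pipeline's estimators recover known
structure under clean sampling assumptions — not that they would do so on
biased, autocorrelated real data.

In a winter-wet world the coldest quarter is also the wettest, so bio19
is inherently collinear with the bio12/bio13/bio16 cluster and the Pearson
step (which keeps the earliest layer) removes it by construction. The
variable-importance recovery experiment is therefore run on the full
19-layer table; the screened pipeline is exercised separately.

## Experiment sizes and numerical choices

* Default world: 90 × 180 cells (2° grid); engine run ≈ 0.7 s; the GA
  recovery experiment (pop 24, 30 generations + polish, 6,625 records)
  ≈ 45 s on one CPU.
* Random-forest experiments use the study's record counts (52 presences,
  156 pseudo-absences) except the permutation null (520/1,560, see above).
* Log floor ε = 1e−3 in the likelihood objective; spin-up tolerance 1e−6;
  Jenks subsample default 2,000; all RNG is numpy `default_rng` seeded
  explicitly, so every experiment is reproducible bit-for-bit for a fixed
  seed and library version.

## Known limitations

* The engine omits diapause, irrigation and degree-day development found
  in full commercial implementations; EI comparisons with those tools are
  qualitative.
* The bucket hydrology (0.8·T evapotranspiration proxy, 100 mm capacity,
  no drainage) is the simplest scheme consistent with the published
  thresholds; absolute EI values depend on it even though threshold
  recovery does not.
* Greedy rarefaction and the greedy Pearson filter are order-dependent by
  design; reorderings of the input can change the retained sets.
* Area accounting treats cells as exact spherical bands on WGS84 decimal
  degrees; no projection or coastline clipping is performed.
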