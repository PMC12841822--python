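"""Synthetic worlds: climate grids, warmed futures, occurrence samples,
region masks.

The generator emulates the gross statistical structure of gridded global
climatology that the pipeline assumes — a latitudinal temperature gradient
with hemisphere-phased sinusoidal seasonality, a precipitation field peaked
at the equator and the mid-latitude storm tracks with a winter-wet seasonal
cycle, and humidity consistent with the rain field — so that every stage
(engine, calibration, correlative model, mapping) can run and be tested
without any download.  It makes no attempt to model spatial autocorrelation
of the noise, topography, or land/ocean geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .climate import MonthlyClimateGrid, BioclimGrid
from .engine import EIGrid
from .occurrences import OccurrenceSet

__all__ = [
    "SyntheticWorldSpec",
    "make_synthetic_climate",
    "warm_future",
    "sample_occurrences_from_ei",
    "sample_presences_logistic",
    "make_region_masks",
    "regions_as_dict",
]


@dataclass(frozen=True)
class SyntheticWorldSpec:
    """Parameters of the synthetic world.

    Temperature: sea-level annual mean ``t_equator − t_gradient·|lat|`` °C
    with seasonal half-amplitude ``seasonal_amp·|lat|/90`` peaking in July
    (north) / January (south), diurnal half-range ``diurnal_half`` and
    cell-independent Gaussian noise ``noise_sd`` on the annual mean.
    Precipitation: annual total with an equatorial peak and mid-latitude
    storm-track peaks, distributed over months with a winter-wet seasonal
    cycle of relative amplitude ``precip_seasonality``.
    """

    nlat: int = 90
    nlon: int = 180
    t_equator: float = 27.0          # °C at lat 0
    t_gradient: float = 0.55         # °C per degree latitude
    seasonal_amp: float = 15.0       # °C half-amplitude at the poles
    diurnal_half: float = 5.0        # (tmax − tmin)/2, °C
    diurnal_noise_sd: float = 1.5    # °C, per-cell noise on the diurnal half-range
    noise_sd: float = 1.0            # °C, per-cell noise on the annual mean
    amp_noise_sd: float = 1.5        # °C, per-cell noise on the seasonal amplitude
    precip_equator: float = 1600.0   # mm/yr amplitude of the equatorial peak
    precip_midlat: float = 700.0     # mm/yr amplitude of the storm-track peaks
    precip_base: float = 120.0       # mm/yr background
    precip_eq_width: float = 18.0    # degrees latitude
    precip_mid_center: float = 45.0  # degrees latitude
    precip_mid_width: float = 12.0   # degrees latitude
    precip_seasonality: float = 0.8  # relative amplitude of the annual cycle
    precip_noise_frac: float = 0.1   # per-cell multiplicative noise on the annual total
    precip_month_noise_frac: float = 0.25  # independent per-cell-month multiplicative noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nlat < 1 or self.nlon < 1:
            raise ValueError("grid shape must be positive")

    @property
    def lat_axis(self) -> np.ndarray:
        step = 180.0 / self.nlat
        return -90.0 + step * (np.arange(self.nlat) + 0.5)

    @property
    def lon_axis(self) -> np.ndarray:
        step = 360.0 / self.nlon
        return -180.0 + step * (np.arange(self.nlon) + 0.5)


_MONTH_MID = np.arange(12) + 0.5  # months as fractions of the year, ×12


def make_synthetic_climate(spec: SyntheticWorldSpec) -> MonthlyClimateGrid:
    """Deterministic (per seed) synthetic monthly climate grid."""
    rng = np.random.default_rng(spec.seed)
    lat = spec.lat_axis[:, None]                       # (nlat, 1)
    nlat, nlon = spec.nlat, spec.nlon

    annual_mean = spec.t_equator - spec.t_gradient * np.abs(lat)
    annual_mean = annual_mean + rng.normal(0.0, spec.noise_sd, size=(nlat, nlon))
    amp = spec.seasonal_amp * np.abs(lat) / 90.0
    if spec.amp_noise_sd > 0:
        # continentality varies along a latitude band
        amp = np.maximum(0.0, amp + rng.normal(0.0, spec.amp_noise_sd, size=(nlat, nlon)))
    else:
        amp = np.broadcast_to(amp, (nlat, nlon)).copy()
    # warmest in July at northern latitudes, January at southern
    phase = np.where(lat >= 0, 6.5, 0.5)
    season = np.cos(2 * np.pi * (_MONTH_MID[:, None, None] - phase[None, :, :]) / 12.0)
    tavg = annual_mean[None] + amp[None, :, :] * season

    annual_precip = (
        spec.precip_equator * np.exp(-((lat / spec.precip_eq_width) ** 2))
        + spec.precip_midlat
        * np.exp(-(((np.abs(lat) - spec.precip_mid_center) / spec.precip_mid_width) ** 2))
        + spec.precip_base
    )
    annual_precip = annual_precip * np.exp(
        rng.normal(0.0, spec.precip_noise_frac, size=(nlat, nlon))
    )
    # winter-wet: precipitation peaks half a year after the temperature peak
    wet_season = -season
    rain = annual_precip[None] / 12.0 * (1.0 + spec.precip_seasonality * wet_season)
    if spec.precip_month_noise_frac > 0:
        rain = rain * np.exp(
            rng.normal(0.0, spec.precip_month_noise_frac, size=(12, nlat, nlon))
        )
    rain = np.maximum(rain, 0.0)

    # humidity loosely tracks the rain cycle; morning air is moister
    wetness = rain / np.maximum(rain.mean(axis=0, keepdims=True), 1e-9)
    rh_base = np.clip(45.0 + 20.0 * wetness, 5.0, 90.0)
    rh09 = np.clip(rh_base + 8.0, 0.0, 100.0)
    rh15 = np.clip(rh_base - 8.0, 0.0, 100.0)

    half = spec.diurnal_half
    if spec.diurnal_noise_sd > 0:
        half = np.maximum(
            0.5, half + rng.normal(0.0, spec.diurnal_noise_sd, size=(nlat, nlon))
        )[None, :, :]
    return MonthlyClimateGrid(
        lat_axis=spec.lat_axis,
        lon_axis=spec.lon_axis,
        tmin=tavg - half,
        tmax=tavg + half,
        rain=rain,
        rh09=rh09,
        rh15=rh15,
    )


def warm_future(
    grid: MonthlyClimateGrid, delta_t: float = 2.0, precip_factor: float = 1.0
) -> MonthlyClimateGrid:
    """Uniformly warmed (and precipitation-scaled) copy of a climate grid,
    standing in for a mid-century scenario."""
    if precip_factor < 0:
        raise ValueError("precip_factor must be non-negative")
    return MonthlyClimateGrid(
        lat_axis=grid.lat_axis.copy(),
        lon_axis=grid.lon_axis.copy(),
        tmin=grid.tmin + delta_t,
        tmax=grid.tmax + delta_t,
        rain=grid.rain * precip_factor,
        rh09=grid.rh09.copy(),
        rh15=grid.rh15.copy(),
        valid=grid.valid.copy(),
    )


def sample_occurrences_from_ei(ei: EIGrid, n: int, seed: int = 0) -> OccurrenceSet:
    """Sample ``n`` presence points with per-cell probability ∝ EI, jittered
    uniformly within the chosen cell."""
    rng = np.random.default_rng(seed)
    weights = np.where(np.isfinite(ei.ei), np.maximum(ei.ei, 0.0), 0.0).ravel()
    total = weights.sum()
    if total <= 0:
        raise ValueError("EI surface has no positive mass to sample from")
    if n == 0:
        return OccurrenceSet(np.empty(0), np.empty(0), np.empty(0, object), np.empty(0, object))
    idx = rng.choice(weights.size, size=n, p=weights / total)
    ilat, ilon = np.unravel_index(idx, ei.ei.shape)
    lat = ei.lat_axis[ilat] + (rng.random(n) - 0.5) * ei.lat_step
    lon = ei.lon_axis[ilon] + (rng.random(n) - 0.5) * ei.lon_step
    lat = np.clip(lat, -90.0, 90.0)
    ids = np.array([f"syn{i}" for i in range(n)], dtype=object)
    return OccurrenceSet(lon, lat, np.array(["presence"] * n, dtype=object), ids)


def sample_presences_logistic(
    bioclim: BioclimGrid,
    coefficients: dict[str, float],
    n_presence: int,
    n_absence: int,
    seed: int = 0,
) -> tuple[OccurrenceSet, np.ndarray]:
    """Presence/absence records with a known logistic dependence on bioclim.

    The per-cell presence probability is the logistic of a linear predictor
    on standardized layers (so coefficient magnitudes are comparable across
    layers); presences are sampled ∝ p, absences ∝ 1 − p, both jittered
    within-cell.  Returns the labelled set and the probability raster.
    """
    unknown = set(coefficients) - set(bioclim.layers)
    if unknown:
        raise ValueError(f"unknown bioclim layer(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    valid = bioclim.valid
    eta = np.zeros(valid.shape)
    for name, coef in coefficients.items():
        layer = bioclim.layers[name]
        vals = layer[valid]
        sd = vals.std()
        if sd == 0:
            if coef != 0:
                raise ValueError(f"layer {name} has zero variance but nonzero coefficient")
            continue
        z = np.zeros(valid.shape)
        z[valid] = (vals - vals.mean()) / sd
        eta = eta + coef * z
    prob = 1.0 / (1.0 + np.exp(-eta))
    prob = np.where(valid, prob, np.nan)

    def draw(weights: np.ndarray, n: int, label: str, prefix: str) -> OccurrenceSet:
        w = np.where(np.isfinite(weights), np.maximum(weights, 0.0), 0.0).ravel()
        if w.sum() <= 0:
            raise ValueError("no probability mass for sampling")
        idx = rng.choice(w.size, size=n, p=w / w.sum())
        ilat, ilon = np.unravel_index(idx, weights.shape)
        dlat = bioclim.lat_axis[1] - bioclim.lat_axis[0] if bioclim.lat_axis.size > 1 else 1.0
        dlon = bioclim.lon_axis[1] - bioclim.lon_axis[0] if bioclim.lon_axis.size > 1 else 1.0
        lat = np.clip(bioclim.lat_axis[ilat] + (rng.random(n) - 0.5) * dlat, -90, 90)
        lon = bioclim.lon_axis[ilon] + (rng.random(n) - 0.5) * dlon
        ids = np.array([f"{prefix}{i}" for i in range(n)], dtype=object)
        return OccurrenceSet(lon, lat, np.array([label] * n, dtype=object), ids)

    pres = draw(prob, n_presence, "presence", "p")
    abs_ = draw(1.0 - prob, n_absence, "pseudo_absence", "a")
    return pres.concat(abs_), prob


def make_region_masks(spec: SyntheticWorldSpec, n_regions: int) -> np.ndarray:
    """Disjoint rectangular "continents": ``n_regions`` equal-width
    longitude bands labelled 1..n (0 = unassigned)."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if n_regions > spec.nlon:
        raise ValueError("more regions than longitude columns")
    labels = np.zeros((spec.nlat, spec.nlon), dtype=int)
    edges = np.linspace(0, spec.nlon, n_regions + 1).round().astype(int)
    for r in range(n_regions):
        labels[:, edges[r] : edges[r + 1]] = r + 1
    return labels


def regions_as_dict(labels: np.ndarray, names: list[str] | None = None) -> dict[str, np.ndarray]:
    """Convert a labelled region raster to {name: boolean mask}."""
    ids = [int(v) for v in np.unique(labels) if v > 0]
    if names is None:
        names = [f"region_{v}" for v in ids]
    if len(names) != len(ids):
        raise ValueError("names length must match number of regions")
    return {name: labels == v for name, v in zip(names, ids)}
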