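"""Mechanistic ecoclimatic suitability engine (CLIMEX-family).

Weekly growth is the product of a trapezoidal Temperature Index (TI, on
weekly mean temperature, thresholds DV0..DV3) and a trapezoidal Moisture
Index (MI, on a weekly soil-moisture bucket, thresholds SM0..SM3).  Four
stresses — cold, heat, dry, wet — accumulate weekly at a fixed rate per unit
exceedance of their thresholds and are capped at 100.  The annual
Ecoclimatic Index per cell is

    EI = GIA * prod_x (1 - S_x / 100),    GIA = 100 * mean_w(TI_w * MI_w)

so a cell is unsuitable (EI = 0) whenever growth is impossible all year or
any one stress saturates.  The default parameter set describes *Cupressus*,
the host genus of the cypress bark beetle.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields, replace

import numpy as np

from .climate import MonthlyClimateGrid, WeeklyClimateSeries, monthly_to_weekly, N_WEEKS

__all__ = [
    "ClimexParameters",
    "EngineConstants",
    "AnnualIndices",
    "EIGrid",
    "temperature_index",
    "moisture_index",
    "soil_moisture_step",
    "soil_moisture_series",
    "annual_growth_index",
    "stress_indices",
    "ecoclimatic_index",
    "EngineInputs",
    "prepare_engine_inputs",
    "run_weekly",
    "run_grid",
]


@dataclass(frozen=True)
class ClimexParameters:
    """Physiological thresholds and stress rates of the ecoclimatic model.

    Defaults are the fitted *Cupressus* host parameterization: growth between
    DV0 = −15 °C and DV3 = 45 °C with optimum 13.6–20.4 °C, soil-moisture
    optimum 0.5–0.9 of bucket capacity, and cold/heat/dry/wet stress
    accumulating beyond −15 °C / 45 °C / 0.05 / 1.5.  Rates are per week;
    cold and dry rates are conventionally printed with a negative sign and
    are used by magnitude.
    """

    DV0: float = -15.0
    DV1: float = 13.6
    DV2: float = 20.4
    DV3: float = 45.0
    SM0: float = 0.05
    SM1: float = 0.5
    SM2: float = 0.9
    SM3: float = 1.5
    TTCS: float = -15.0
    THCS: float = -0.125
    TTHS: float = 45.0
    THHS: float = 0.015
    SMDS: float = 0.05
    HDS: float = -0.005
    SMWS: float = 1.5
    HWS: float = 0.012

    def __post_init__(self) -> None:
        if not (self.DV0 <= self.DV1 <= self.DV2 <= self.DV3):
            raise ValueError("temperature thresholds must satisfy DV0 <= DV1 <= DV2 <= DV3")
        if not (self.SM0 <= self.SM1 <= self.SM2 <= self.SM3):
            raise ValueError("moisture thresholds must satisfy SM0 <= SM1 <= SM2 <= SM3")
        for f in dc_fields(self):
            if not np.isfinite(getattr(self, f.name)):
                raise ValueError(f"parameter {f.name} must be finite")

    @classmethod
    def names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dc_fields(cls))

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in dc_fields(self)}

    def replace(self, **kwargs: float) -> "ClimexParameters":
        return replace(self, **kwargs)

    def write(self, path) -> None:
        """Write a flat ``KEY = value`` config file keyed by parameter symbol."""
        with open(path, "w") as fh:
            for name, value in self.to_dict().items():
                fh.write(f"{name} = {value}\n")

    @classmethod
    def read(cls, path) -> "ClimexParameters":
        values: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, raw = line.partition("=")
                values[key.strip()] = float(raw)
        unknown = set(values) - set(cls.names())
        if unknown:
            raise ValueError(f"unknown parameter(s) in config: {sorted(unknown)}")
        return cls(**values)


@dataclass(frozen=True)
class EngineConstants:
    """Fixed hydrology/numerics of the engine (not fitted to occurrences).

    ``et_coefficient`` is the temperature-proxy potential evapotranspiration
    slope (mm week⁻¹ °C⁻¹); ``bucket_capacity_mm`` converts the weekly water
    balance to the dimensionless moisture state; ``sm_cap`` bounds that state.
    """

    et_coefficient: float = 0.8
    bucket_capacity_mm: float = 100.0
    sm_cap: float = 2.0
    spinup_tol: float = 1e-6
    max_spinup_cycles: int = 10


DEFAULT_CONSTANTS = EngineConstants()


@dataclass
class AnnualIndices:
    """Weekly and annual indices for a single cell."""

    TIw: np.ndarray
    MIw: np.ndarray
    GIw: np.ndarray
    GIA: float
    CS: float
    HS: float
    DS: float
    WS: float
    EI: float


@dataclass
class EIGrid:
    """Annual Ecoclimatic Index per cell, in [0, 100], NaN where nodata."""

    lat_axis: np.ndarray
    lon_axis: np.ndarray
    ei: np.ndarray
    valid: np.ndarray

    @property
    def lat_step(self) -> float:
        return float(self.lat_axis[1] - self.lat_axis[0]) if self.lat_axis.size > 1 else 1.0

    @property
    def lon_step(self) -> float:
        return float(self.lon_axis[1] - self.lon_axis[0]) if self.lon_axis.size > 1 else 1.0


def _trapezoid(x, lo, opt_lo, opt_hi, hi):
    """Piecewise-linear response: 0 outside (lo, hi), 1 on [opt_lo, opt_hi]."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    if opt_lo > lo:
        rising = (x > lo) & (x < opt_lo)
        out = np.where(rising, (x - lo) / (opt_lo - lo), out)
    if hi > opt_hi:
        falling = (x > opt_hi) & (x < hi)
        out = np.where(falling, (hi - x) / (hi - opt_hi), out)
    out = np.where((x >= opt_lo) & (x <= opt_hi), 1.0, out)
    return out if out.ndim else float(out)


def temperature_index(t_week, p: ClimexParameters):
    """Weekly Temperature Index: trapezoid over (DV0, DV1, DV2, DV3)."""
    return _trapezoid(t_week, p.DV0, p.DV1, p.DV2, p.DV3)


def moisture_index(m, p: ClimexParameters):
    """Weekly Moisture Index: trapezoid over (SM0, SM1, SM2, SM3)."""
    return _trapezoid(m, p.SM0, p.SM1, p.SM2, p.SM3)


def soil_moisture_step(
    m_prev,
    rain_week,
    t_week,
    capacity_mm: float = DEFAULT_CONSTANTS.bucket_capacity_mm,
    constants: EngineConstants = DEFAULT_CONSTANTS,
):
    """One weekly update of the dimensionless soil-moisture bucket.

    m_new = clamp(m_prev + (rain − Epot)/capacity, 0, sm_cap) with the
    temperature-proxy potential evapotranspiration Epot = max(0, 0.8·T)
    mm/week.  There is no drainage term: surplus beyond the cap is shed.
    """
    rain_week = np.asarray(rain_week, dtype=float)
    if np.any(rain_week < 0):
        raise ValueError("weekly rain must be non-negative")
    epot = np.maximum(0.0, constants.et_coefficient * np.asarray(t_week, dtype=float))
    m_new = np.clip(m_prev + (rain_week - epot) / capacity_mm, 0.0, constants.sm_cap)
    return m_new if np.ndim(m_new) else float(m_new)


def soil_moisture_series(
    rain: np.ndarray,
    tavg: np.ndarray,
    constants: EngineConstants = DEFAULT_CONSTANTS,
    m_init: float = 1.0,
) -> np.ndarray:
    """Annual weekly soil-moisture trajectory after spin-up.

    The annual cycle is repeated from ``m_init`` until the week-1 moisture
    changes by less than ``spinup_tol`` between cycles (or the cycle budget
    is exhausted), then one more pass records the trajectory.  Arrays are
    shaped (52, ...) and the computation is vectorized over trailing axes.
    """
    rain = np.asarray(rain, dtype=float)
    tavg = np.asarray(tavg, dtype=float)
    if rain.shape[0] != N_WEEKS:
        raise ValueError(f"expected {N_WEEKS} weekly values, got {rain.shape[0]}")
    m = np.full(rain.shape[1:] if rain.ndim > 1 else (), m_init, dtype=float)
    m_week1_prev = np.full_like(m, np.inf, dtype=float)
    for _ in range(constants.max_spinup_cycles):
        m_week1 = None
        for w in range(N_WEEKS):
            m = soil_moisture_step(m, rain[w], tavg[w], constants.bucket_capacity_mm, constants)
            if w == 0:
                m_week1 = np.asarray(m, dtype=float).copy()
        if np.all(np.abs(m_week1 - m_week1_prev) < constants.spinup_tol):
            break
        m_week1_prev = m_week1
    traj = np.empty_like(rain)
    for w in range(N_WEEKS):
        m = soil_moisture_step(m, rain[w], tavg[w], constants.bucket_capacity_mm, constants)
        traj[w] = m
    return traj


def annual_growth_index(gi_weekly: np.ndarray) -> float:
    """Annual Growth Index: 100 × mean of the 52 weekly growth indices."""
    gi_weekly = np.asarray(gi_weekly, dtype=float)
    if gi_weekly.shape[0] != N_WEEKS:
        raise ValueError(f"expected {N_WEEKS} weekly GI values, got {gi_weekly.shape[0]}")
    return 100.0 * gi_weekly.mean(axis=0)


def stress_indices(tavg: np.ndarray, moisture: np.ndarray, p: ClimexParameters):
    """Annual cold/heat/dry/wet stress, each in [0, 100].

    Weekly increment = |rate| × positive exceedance of the stress threshold
    (TTCS downward for cold, TTHS upward for heat, SMDS downward for dry,
    SMWS upward for wet); the annual sum is capped at 1 and scaled to 100.
    Printed cold/dry rates are negative; magnitudes are used.
    """
    tavg = np.asarray(tavg, dtype=float)
    moisture = np.asarray(moisture, dtype=float)
    cs = abs(p.THCS) * np.maximum(0.0, p.TTCS - tavg).sum(axis=0)
    hs = abs(p.THHS) * np.maximum(0.0, tavg - p.TTHS).sum(axis=0)
    ds = abs(p.HDS) * np.maximum(0.0, p.SMDS - moisture).sum(axis=0)
    ws = abs(p.HWS) * np.maximum(0.0, moisture - p.SMWS).sum(axis=0)
    cap = lambda s: np.minimum(1.0, s) * 100.0  # noqa: E731
    return cap(cs), cap(hs), cap(ds), cap(ws)


def ecoclimatic_index(gia, cs, hs, ds, ws):
    """EI = GIA × Π(1 − S/100), clamped to [0, 100]."""
    factor = (1 - np.asarray(cs) / 100.0) * (1 - np.asarray(hs) / 100.0)
    factor = factor * (1 - np.asarray(ds) / 100.0) * (1 - np.asarray(ws) / 100.0)
    ei = np.clip(np.asarray(gia) * factor, 0.0, 100.0)
    return ei if np.ndim(ei) else float(ei)


@dataclass
class EngineInputs:
    """Parameter-independent weekly drivers, precomputed once per climate grid.

    The weekly interpolation and the soil-moisture trajectory depend only on
    the climate and the fixed engine constants, never on the fitted
    thresholds, so calibration loops reuse this object across candidate
    parameter sets.
    """

    lat_axis: np.ndarray
    lon_axis: np.ndarray
    tavg: np.ndarray      # (52, ncells) valid cells only
    moisture: np.ndarray  # (52, ncells)
    valid: np.ndarray     # (nlat, nlon) bool


def prepare_engine_inputs(
    climate: MonthlyClimateGrid, constants: EngineConstants = DEFAULT_CONSTANTS
) -> EngineInputs:
    weekly = monthly_to_weekly(climate)
    v = weekly.valid
    tavg = weekly.tavg[:, v]
    rain = weekly.rain[:, v]
    moisture = soil_moisture_series(rain, tavg, constants)
    return EngineInputs(
        lat_axis=weekly.lat_axis,
        lon_axis=weekly.lon_axis,
        tavg=tavg,
        moisture=moisture,
        valid=v,
    )


def run_weekly(tavg: np.ndarray, moisture: np.ndarray, p: ClimexParameters) -> AnnualIndices:
    """Annual indices from weekly mean temperature and soil moisture.

    Accepts (52,) vectors for a single cell or (52, n) stacks.
    """
    ti = temperature_index(tavg, p)
    mi = moisture_index(moisture, p)
    gi = ti * mi
    gia = annual_growth_index(gi)
    cs, hs, ds, ws = stress_indices(tavg, moisture, p)
    ei = ecoclimatic_index(gia, cs, hs, ds, ws)
    return AnnualIndices(TIw=ti, MIw=mi, GIw=gi, GIA=gia, CS=cs, HS=hs, DS=ds, WS=ws, EI=ei)


def run_grid(
    climate: MonthlyClimateGrid | EngineInputs,
    p: ClimexParameters,
    constants: EngineConstants = DEFAULT_CONSTANTS,
) -> EIGrid:
    """Ecoclimatic Index over a whole grid.

    Accepts either a monthly climate grid or precomputed ``EngineInputs``
    (the two give identical results; the latter skips re-interpolation).
    """
    inputs = (
        climate
        if isinstance(climate, EngineInputs)
        else prepare_engine_inputs(climate, constants)
    )
    indices = run_weekly(inputs.tavg, inputs.moisture, p)
    ei = np.full(inputs.valid.shape, np.nan)
    ei[inputs.valid] = indices.EI
    return EIGrid(
        lat_axis=inputs.lat_axis.copy(),
        lon_axis=inputs.lon_axis.copy(),
        ei=ei,
        valid=inputs.valid.copy(),
    )


def write_ei(grid: EIGrid, path) -> None:
    """Write EI as CSV (lon, lat, ei), valid cells only."""
    import pandas as pd

    lon2, lat2 = np.meshgrid(grid.lon_axis, grid.lat_axis)
    ok = grid.valid & np.isfinite(grid.ei)
    pd.DataFrame({"lon": lon2[ok], "lat": lat2[ok], "ei": grid.ei[ok]}).to_csv(path, index=False)


def read_ei(path) -> EIGrid:
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    lat_axis = np.unique(df["lat"].to_numpy(dtype=float))
    lon_axis = np.unique(df["lon"].to_numpy(dtype=float))
    ei = np.full((lat_axis.size, lon_axis.size), np.nan)
    ilat = np.searchsorted(lat_axis, df["lat"].to_numpy(dtype=float))
    ilon = np.searchsorted(lon_axis, df["lon"].to_numpy(dtype=float))
    ei[ilat, ilon] = df["ei"].to_numpy(dtype=float)
    return EIGrid(lat_axis=lat_axis, lon_axis=lon_axis, ei=ei, valid=np.isfinite(ei))
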