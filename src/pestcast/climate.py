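"""Gridded monthly climate: containers, CSV I/O, weekly interpolation, bioclim layers.

The monthly grid is the common currency of the pipeline: the mechanistic
engine interpolates it to weekly series, and the correlative model consumes
the 19 bioclimatic summary layers derived from it.  All layers live on a
regular lat/lon grid (cell centers at the axis coordinates, WGS84 decimal
degrees); invalid cells (ocean, missing data) carry NaN and a False entry in
the validity mask, and every operation propagates that nodata state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyClimateGrid",
    "WeeklyClimateSeries",
    "BioclimGrid",
    "BIOCLIM_NAMES",
    "read_climate",
    "write_climate",
    "monthly_to_weekly",
    "compute_bioclim",
]

#: days per calendar month in the fixed 365-day model year
MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)
DAYS_PER_YEAR = 365.0
N_WEEKS = 52
WEEK_LEN = DAYS_PER_YEAR / N_WEEKS

CLIMATE_VARIABLES = ("tmin", "tmax", "rain", "rh09", "rh15")

BIOCLIM_NAMES = tuple(f"bio{i}" for i in range(1, 20))


class ClimateFormatError(ValueError):
    """Raised when an input table violates the grid contract."""


def _check_axis(axis: np.ndarray, name: str) -> None:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 1:
        raise ClimateFormatError(f"{name} axis must be a 1-D array")
    if axis.size > 1:
        steps = np.diff(axis)
        if np.any(steps <= 0):
            raise ClimateFormatError(f"{name} axis must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
            raise ClimateFormatError(f"{name} axis must have a constant step")


@dataclass
class MonthlyClimateGrid:
    """Monthly Tmin/Tmax/precipitation/relative-humidity fields on a lat/lon grid.

    Arrays are shaped ``(12, nlat, nlon)``; ``lat_axis`` is ascending.
    ``rh09``/``rh15`` are relative humidity (percent) observed at 09:00 and
    15:00 local time; the engine uses their mean as its single humidity input.
    """

    lat_axis: np.ndarray
    lon_axis: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    rain: np.ndarray
    rh09: np.ndarray
    rh15: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        for name in CLIMATE_VARIABLES:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.valid is None:
            stacked = np.stack([getattr(self, v) for v in CLIMATE_VARIABLES])
            self.valid = np.all(np.isfinite(stacked), axis=(0, 1))
        self.valid = np.asarray(self.valid, dtype=bool)
        self.validate()

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat_axis.size, self.lon_axis.size

    @property
    def tavg(self) -> np.ndarray:
        return 0.5 * (self.tmin + self.tmax)

    @property
    def lat_step(self) -> float:
        return float(self.lat_axis[1] - self.lat_axis[0]) if self.lat_axis.size > 1 else 1.0

    @property
    def lon_step(self) -> float:
        return float(self.lon_axis[1] - self.lon_axis[0]) if self.lon_axis.size > 1 else 1.0

    def validate(self) -> None:
        _check_axis(self.lat_axis, "lat")
        _check_axis(self.lon_axis, "lon")
        nlat, nlon = self.shape
        for name in CLIMATE_VARIABLES:
            arr = getattr(self, name)
            if arr.shape != (12, nlat, nlon):
                raise ClimateFormatError(
                    f"{name} has shape {arr.shape}, expected (12, {nlat}, {nlon})"
                )
        if self.valid.shape != (nlat, nlon):
            raise ClimateFormatError("validity mask shape mismatch")
        v = self.valid
        if np.any(self.tmax[:, v] < self.tmin[:, v]):
            bad = np.argwhere(np.any(self.tmax < self.tmin, axis=0) & v)[0]
            raise ClimateFormatError(
                f"tmax < tmin at cell (lat={self.lat_axis[bad[0]]}, lon={self.lon_axis[bad[1]]})"
            )
        if np.any(self.rain[:, v] < 0):
            raise ClimateFormatError("negative precipitation in a valid cell")
        for name in ("rh09", "rh15"):
            arr = getattr(self, name)
            if np.any((arr[:, v] < 0) | (arr[:, v] > 100)):
                raise ClimateFormatError(f"{name} outside [0, 100] in a valid cell")

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """Index of the grid cell containing a point (nearest center)."""
        i = int(np.argmin(np.abs(self.lat_axis - lat)))
        j = int(np.argmin(np.abs(self.lon_axis - lon)))
        return i, j


@dataclass
class WeeklyClimateSeries:
    """52-week series per cell, interpolated from the monthly grid."""

    lat_axis: np.ndarray
    lon_axis: np.ndarray
    tavg: np.ndarray  # (52, nlat, nlon)
    tmin: np.ndarray
    tmax: np.ndarray
    rain: np.ndarray  # mm per week
    rh: np.ndarray    # mean of 09:00 and 15:00 RH, percent
    valid: np.ndarray


@dataclass
class BioclimGrid:
    """The 19 standard bioclimatic layers on the shared grid."""

    lat_axis: np.ndarray
    lon_axis: np.ndarray
    layers: dict[str, np.ndarray]
    valid: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers


# ---------------------------------------------------------------------------
# I/O — long-format CSV (lon, lat, variable, month, value)
# ---------------------------------------------------------------------------

def write_climate(grid: MonthlyClimateGrid, path) -> None:
    """Write a grid as long-format CSV with columns lon, lat, variable, month, value."""
    rows = []
    nlat, nlon = grid.shape
    lon2, lat2 = np.meshgrid(grid.lon_axis, grid.lat_axis)
    for name in CLIMATE_VARIABLES:
        arr = getattr(grid, name)
        for m in range(12):
            vals = arr[m]
            ok = grid.valid & np.isfinite(vals)
            rows.append(
                pd.DataFrame(
                    {
                        "lon": lon2[ok],
                        "lat": lat2[ok],
                        "variable": name,
                        "month": m + 1,
                        "value": vals[ok],
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_climate(path, format_tag: str = "csv") -> MonthlyClimateGrid:
    """Read a monthly climate grid from long-format CSV.

    The grid axes are reconstructed from the unique coordinates present;
    cells without a complete 12-month record of every variable are nodata.
    """
    if format_tag != "csv":
        raise ClimateFormatError(f"unsupported format_tag: {format_tag!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"lon", "lat", "variable", "month", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ClimateFormatError(f"missing columns: {sorted(missing)}")
    present = set(df["variable"].unique())
    absent = [v for v in CLIMATE_VARIABLES if v not in present]
    if absent:
        raise ClimateFormatError(f"missing climate variable(s): {absent}")

    lat_axis = np.unique(df["lat"].to_numpy(dtype=float))
    lon_axis = np.unique(df["lon"].to_numpy(dtype=float))
    _check_axis(lat_axis, "lat")
    _check_axis(lon_axis, "lon")
    nlat, nlon = lat_axis.size, lon_axis.size
    ilat = np.searchsorted(lat_axis, df["lat"].to_numpy(dtype=float))
    ilon = np.searchsorted(lon_axis, df["lon"].to_numpy(dtype=float))
    imonth = df["month"].to_numpy(dtype=int) - 1
    if imonth.min() < 0 or imonth.max() > 11:
        raise ClimateFormatError("month column must be in 1..12")

    arrays = {v: np.full((12, nlat, nlon), np.nan) for v in CLIMATE_VARIABLES}
    codes = df["variable"].to_numpy()
    values = df["value"].to_numpy(dtype=float)
    for v in CLIMATE_VARIABLES:
        sel = codes == v
        arrays[v][imonth[sel], ilat[sel], ilon[sel]] = values[sel]
    return MonthlyClimateGrid(lat_axis=lat_axis, lon_axis=lon_axis, **arrays)


# ---------------------------------------------------------------------------
# Monthly -> weekly interpolation
# ---------------------------------------------------------------------------

def _month_edges() -> tuple[np.ndarray, np.ndarray]:
    ends = np.cumsum(MONTH_DAYS)
    starts = ends - MONTH_DAYS
    return starts, ends


def _weekly_state(monthly: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation of a (12, ...) monthly state variable
    to 52 weekly values, anchored at mid-month days, periodic in the year."""
    starts, _ = _month_edges()
    mids = starts + MONTH_DAYS / 2.0
    # periodic padding: December of the previous year, January of the next
    anchors = np.concatenate([[mids[-1] - DAYS_PER_YEAR], mids, [mids[0] + DAYS_PER_YEAR]])
    week_mid = (np.arange(N_WEEKS) + 0.5) * WEEK_LEN
    flat = monthly.reshape(12, -1)
    padded = np.concatenate([flat[-1:], flat, flat[:1]], axis=0)
    out = np.empty((N_WEEKS, flat.shape[1]))
    for k in range(flat.shape[1]):
        out[:, k] = np.interp(week_mid, anchors, padded[:, k])
    return out.reshape((N_WEEKS,) + monthly.shape[1:])


def _weekly_flux(monthly: np.ndarray) -> np.ndarray:
    """Allocate a (12, ...) monthly flux (mm/month) to 52 weeks proportionally
    to the number of days each month contributes to each week."""
    starts, ends = _month_edges()
    week_lo = np.arange(N_WEEKS) * WEEK_LEN
    week_hi = week_lo + WEEK_LEN
    # overlap[w, m] = days of month m inside week w
    overlap = np.maximum(
        0.0,
        np.minimum(week_hi[:, None], ends[None, :]) - np.maximum(week_lo[:, None], starts[None, :]),
    )
    weights = overlap / MONTH_DAYS[None, :]  # fraction of month m in week w
    flat = monthly.reshape(12, -1)
    out = weights @ flat
    return out.reshape((N_WEEKS,) + monthly.shape[1:])


def monthly_to_weekly(grid: MonthlyClimateGrid) -> WeeklyClimateSeries:
    """Interpolate the monthly grid to a 52-week year.

    Temperatures and humidity are treated as state variables (mid-month
    anchored piecewise-linear interpolation, periodic across the year
    boundary); precipitation is a flux, divided across the weeks overlapping
    each month in proportion to days, which conserves the annual total.
    """
    rh = 0.5 * (grid.rh09 + grid.rh15)
    return WeeklyClimateSeries(
        lat_axis=grid.lat_axis,
        lon_axis=grid.lon_axis,
        tavg=_weekly_state(grid.tavg),
        tmin=_weekly_state(grid.tmin),
        tmax=_weekly_state(grid.tmax),
        rain=_weekly_flux(grid.rain),
        rh=_weekly_state(rh),
        valid=grid.valid.copy(),
    )


# ---------------------------------------------------------------------------
# Bioclim layers
# ---------------------------------------------------------------------------

def _quarter_stats(tavg: np.ndarray, rain: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean temperature and precipitation total of the 12 wrap-around quarters.

    Quarter q = calendar months (q, q+1, q+2) mod 12. Returns arrays shaped
    (12, ...).
    """
    qt = np.empty_like(tavg)
    qp = np.empty_like(rain)
    for q in range(12):
        idx = [(q + k) % 12 for k in range(3)]
        qt[q] = tavg[idx].mean(axis=0)
        qp[q] = rain[idx].sum(axis=0)
    return qt, qp


def compute_bioclim(grid: MonthlyClimateGrid) -> BioclimGrid:
    """Derive the 19 standard bioclimatic layers from monthly climate.

    Quarters are any 3 consecutive calendar months, wrapping across the year
    boundary; the extreme quarter is chosen by quarter mean (temperature) or
    sum (precipitation), ties broken toward the earliest start month
    (``argmax``/``argmin`` return the first extreme).
    """
    tavg, tmin, tmax, rain = grid.tavg, grid.tmin, grid.tmax, grid.rain
    qt, qp = _quarter_stats(tavg, rain)

    def pick(source: np.ndarray, selector_idx: np.ndarray) -> np.ndarray:
        return np.take_along_axis(source, selector_idx[None], axis=0)[0]

    wettest_q = np.argmax(qp, axis=0)
    driest_q = np.argmin(qp, axis=0)
    warmest_q = np.argmax(qt, axis=0)
    coldest_q = np.argmin(qt, axis=0)

    layers: dict[str, np.ndarray] = {}
    layers["bio1"] = tavg.mean(axis=0)
    layers["bio2"] = (tmax - tmin).mean(axis=0)
    layers["bio5"] = tmax.max(axis=0)
    layers["bio6"] = tmin.min(axis=0)
    layers["bio7"] = layers["bio5"] - layers["bio6"]
    with np.errstate(divide="ignore", invalid="ignore"):
        layers["bio3"] = np.where(
            layers["bio7"] != 0, layers["bio2"] / layers["bio7"] * 100.0, 0.0
        )
    layers["bio4"] = tavg.std(axis=0, ddof=0) * 100.0
    layers["bio8"] = pick(qt, wettest_q)
    layers["bio9"] = pick(qt, driest_q)
    layers["bio10"] = pick(qt, warmest_q)
    layers["bio11"] = pick(qt, coldest_q)
    layers["bio12"] = rain.sum(axis=0)
    layers["bio13"] = rain.max(axis=0)
    layers["bio14"] = rain.min(axis=0)
    mean_rain = rain.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        layers["bio15"] = np.where(
            mean_rain > 0, rain.std(axis=0, ddof=0) / mean_rain * 100.0, 0.0
        )
    layers["bio16"] = pick(qp, wettest_q)
    layers["bio17"] = pick(qp, driest_q)
    layers["bio18"] = pick(qp, warmest_q)
    layers["bio19"] = pick(qp, coldest_q)

    invalid = ~grid.valid
    for name in BIOCLIM_NAMES:
        layers[name] = np.where(invalid, np.nan, layers[name])
    return BioclimGrid(
        lat_axis=grid.lat_axis.copy(),
        lon_axis=grid.lon_axis.copy(),
        layers=layers,
        valid=grid.valid.copy(),
    )


def write_bioclim(bioclim: BioclimGrid, path) -> None:
    """Write bioclim layers as long-format CSV (lon, lat, layer, value)."""
    lon2, lat2 = np.meshgrid(bioclim.lon_axis, bioclim.lat_axis)
    rows = []
    for name in BIOCLIM_NAMES:
        vals = bioclim.layers[name]
        ok = bioclim.valid & np.isfinite(vals)
        rows.append(
            pd.DataFrame({"lon": lon2[ok], "lat": lat2[ok], "layer": name, "value": vals[ok]})
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_bioclim(path) -> BioclimGrid:
    df = pd.read_csv(path, float_precision="round_trip")
    lat_axis = np.unique(df["lat"].to_numpy(dtype=float))
    lon_axis = np.unique(df["lon"].to_numpy(dtype=float))
    ilat = np.searchsorted(lat_axis, df["lat"].to_numpy(dtype=float))
    ilon = np.searchsorted(lon_axis, df["lon"].to_numpy(dtype=float))
    layers = {name: np.full((lat_axis.size, lon_axis.size), np.nan) for name in BIOCLIM_NAMES}
    codes = df["layer"].to_numpy()
    values = df["value"].to_numpy(dtype=float)
    for name in BIOCLIM_NAMES:
        sel = codes == name
        layers[name][ilat[sel], ilon[sel]] = values[sel]
    valid = np.all(np.stack([np.isfinite(layers[n]) for n in BIOCLIM_NAMES]), axis=0)
    return BioclimGrid(lat_axis=lat_axis, lon_axis=lon_axis, layers=layers, valid=valid)
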