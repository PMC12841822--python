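"""Suitability mapping: natural-breaks classification, host-mask overlay,
change maps, and latitude-weighted area accounting.

The continuous presence-probability raster from the correlative model is cut
into five ordinal classes (unsuitable, very low, low, medium, high) by exact
Jenks natural breaks; the mechanistic host model supplies a binary mask
(EI > 0) restricting the pest map to cells where the host can persist; and
per-region areas are summed with the spherical-band cell-area formula so
that percent changes between epochs can be reported per continent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import EIGrid

EARTH_RADIUS_KM = 6371.0

CLASS_NAMES = ("unsuitable", "very_low", "low", "medium", "high")

__all__ = [
    "CLASS_NAMES",
    "ClassifiedRaster",
    "AreaReport",
    "jenks_breaks",
    "classify",
    "host_mask",
    "apply_mask",
    "difference_map",
    "cell_area",
    "grid_cell_areas",
    "percent_change",
    "area_report",
    "area_report_from_totals",
]


@dataclass
class ClassifiedRaster:
    """5-class ordinal suitability raster; codes 0..4, -1 where nodata."""

    lat_axis: np.ndarray
    lon_axis: np.ndarray
    codes: np.ndarray  # int, -1 = nodata
    breaks: np.ndarray  # the 4 interior break values

    @property
    def valid(self) -> np.ndarray:
        return self.codes >= 0


@dataclass
class AreaReport:
    """Areas (10⁴ km²) per region × class plus suitable totals and % change."""

    per_class: pd.DataFrame       # region, class, area_current, area_future
    totals: pd.DataFrame          # region, suitable_current, suitable_future, percent_change
    min_class: int

    def to_json_dict(self) -> dict:
        return {
            "min_class": self.min_class,
            "per_class": self.per_class.to_dict(orient="records"),
            "totals": self.totals.to_dict(orient="records"),
        }


# ---------------------------------------------------------------------------
# Jenks natural breaks
# ---------------------------------------------------------------------------

def jenks_breaks(values, k: int = 5, max_n: int | None = None, seed: int = 0) -> np.ndarray:
    """Exact Jenks natural breaks minimizing within-class sum of squares.

    Dynamic programming over the sorted values; returns the ``k-1`` interior
    break values, each the minimum of its upper class, so that half-open
    classification ``[b_i, b_{i+1})`` reproduces the optimal partition.
    When multiple partitions tie, the one with the lowest break values is
    chosen.  ``max_n`` optionally subsamples large inputs (evenly across the
    sorted order) before the exact optimization, as map classifiers
    conventionally do.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if np.unique(x).size < k:
        raise ValueError(f"need at least {k} distinct finite values, got {np.unique(x).size}")
    x = np.sort(x)
    if max_n is not None and x.size > max_n:
        idx = np.linspace(0, x.size - 1, max_n).round().astype(int)
        x = x[idx]
    n = x.size
    pref = np.concatenate([[0.0], np.cumsum(x)])
    pref2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i: np.ndarray, j: int) -> np.ndarray:
        """Within-class SSE of x[i:j] for a vector of starts i (exclusive end j)."""
        cnt = j - i
        s = pref[j] - pref[i]
        s2 = pref2[j] - pref2[i]
        return s2 - s * s / np.maximum(cnt, 1)

    # cost[c, j] = minimal SSE of splitting x[:j] into c classes
    inf = np.inf
    cost = np.full((k + 1, n + 1), inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    starts = np.arange(n + 1)
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            i = starts[c - 1 : j]  # last class is x[i:j], needs i >= c-1
            cand = cost[c - 1, c - 1 : j] + sse(i, j)
            # ties toward the smallest i -> lowest break values
            best = int(np.argmin(cand))
            cost[c, j] = cand[best]
            split[c, j] = c - 1 + best
    # backtrack class start indices
    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = split[c, j]
        bounds.append(j)
    bounds.reverse()  # [0, i1, ..., i_{k-1}, n]
    breaks = np.array([x[i] for i in bounds[1:-1]], dtype=float)
    return breaks


def classify(raster, breaks, lat_axis=None, lon_axis=None) -> ClassifiedRaster:
    """Assign each cell to one of 5 ordinal classes by half-open intervals.

    ``codes = #{breaks <= value}``: a value below the first break is
    unsuitable (0); a value equal to a break joins the upper class.
    Accepts a bare array plus axes, or any object with ``lat_axis``,
    ``lon_axis`` and a values array attribute.
    """
    if hasattr(raster, "lat_axis"):
        lat_axis = raster.lat_axis
        lon_axis = raster.lon_axis
        values = getattr(raster, "ei", None)
        if values is None:
            values = raster.values  # type: ignore[union-attr]
    else:
        values = np.asarray(raster, dtype=float)
        if lat_axis is None or lon_axis is None:
            raise ValueError("lat_axis and lon_axis required for a bare array")
    values = np.asarray(values, dtype=float)
    breaks = np.asarray(breaks, dtype=float)
    if breaks.ndim != 1 or np.any(np.diff(breaks) <= 0):
        raise ValueError("breaks must be strictly increasing")
    codes = np.searchsorted(breaks, values, side="right").astype(int)
    codes[~np.isfinite(values)] = -1
    return ClassifiedRaster(
        lat_axis=np.asarray(lat_axis, float),
        lon_axis=np.asarray(lon_axis, float),
        codes=codes,
        breaks=breaks,
    )


# ---------------------------------------------------------------------------
# Host mask overlay
# ---------------------------------------------------------------------------

def host_mask(ei: EIGrid) -> np.ndarray:
    """Binary host-presence raster: 1 where EI > 0, 0 where EI = 0, NaN nodata."""
    mask = np.where(ei.ei > 0, 1.0, 0.0)
    mask[~np.isfinite(ei.ei)] = np.nan
    return mask


def apply_mask(suitability: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Restrict a suitability raster to host-suitable cells.

    Cells where the mask is 0 get probability 0 (hence class unsuitable
    after classification); mask = 1 cells are unchanged; nodata propagates.
    """
    suitability = np.asarray(suitability, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if suitability.shape != mask.shape:
        raise ValueError(f"grid mismatch: {suitability.shape} vs {mask.shape}")
    out = np.where(mask == 0, 0.0, suitability)
    out = np.where(np.isnan(mask) | np.isnan(suitability), np.nan, out)
    return out


def difference_map(current: ClassifiedRaster, future: ClassifiedRaster) -> np.ndarray:
    """Signed ordinal change per cell: future code − current code ∈ [−4, 4]."""
    if current.codes.shape != future.codes.shape:
        raise ValueError("grid mismatch between epochs")
    diff = future.codes.astype(float) - current.codes.astype(float)
    diff[(current.codes < 0) | (future.codes < 0)] = np.nan
    return diff


# ---------------------------------------------------------------------------
# Areas
# ---------------------------------------------------------------------------

def cell_area(lat_center, dlat: float, dlon: float) -> np.ndarray:
    """Spherical-band area (km²) of a dlat × dlon cell centered at lat_center.

    A = R² · Δλ · (sin φ_top − sin φ_bottom), with the band clipped to the
    poles.
    """
    lat_center = np.asarray(lat_center, dtype=float)
    top = np.radians(np.clip(lat_center + abs(dlat) / 2.0, -90.0, 90.0))
    bot = np.radians(np.clip(lat_center - abs(dlat) / 2.0, -90.0, 90.0))
    a = EARTH_RADIUS_KM**2 * np.radians(abs(dlon)) * (np.sin(top) - np.sin(bot))
    return a if np.ndim(a) else float(a)


def grid_cell_areas(lat_axis: np.ndarray, lon_axis: np.ndarray) -> np.ndarray:
    """(nlat, nlon) array of cell areas in km² for a regular grid."""
    lat_axis = np.asarray(lat_axis, float)
    lon_axis = np.asarray(lon_axis, float)
    dlat = float(lat_axis[1] - lat_axis[0]) if lat_axis.size > 1 else 1.0
    dlon = float(lon_axis[1] - lon_axis[0]) if lon_axis.size > 1 else 1.0
    band = cell_area(lat_axis, dlat, dlon)
    return np.repeat(np.asarray(band)[:, None], lon_axis.size, axis=1)


def percent_change(current: float, future: float) -> float:
    """(future − current) / current × 100."""
    if current == 0:
        raise ZeroDivisionError("current area is zero; percent change undefined")
    return (future - current) / current * 100.0


def area_report(
    current: ClassifiedRaster,
    future: ClassifiedRaster,
    region_masks: dict[str, np.ndarray],
    min_class: int = 1,
) -> AreaReport:
    """Per-region, per-class areas (10⁴ km²) for two epochs with % change.

    ``region_masks`` maps region name → boolean cell mask; masks must be
    pairwise disjoint.  "Suitable area" is the total over classes with code
    ≥ ``min_class`` (default: everything above unsuitable).
    """
    shape = current.codes.shape
    occupancy = np.zeros(shape, dtype=int)
    for name, m in region_masks.items():
        if m.shape != shape:
            raise ValueError(f"region {name!r} mask shape mismatch")
        occupancy += m.astype(int)
    if np.any(occupancy > 1):
        raise ValueError("region masks overlap")
    areas = grid_cell_areas(current.lat_axis, current.lon_axis)
    rows = []
    totals = []
    for name, m in region_masks.items():
        rec = {"region": name}
        suit_cur = suit_fut = 0.0
        for code, cls in enumerate(CLASS_NAMES):
            a_cur = areas[m & (current.codes == code)].sum() / 1e4
            a_fut = areas[m & (future.codes == code)].sum() / 1e4
            rows.append(
                {"region": name, "class": cls, "area_current": a_cur, "area_future": a_fut}
            )
            if code >= min_class:
                suit_cur += a_cur
                suit_fut += a_fut
        rec.update(
            suitable_current=suit_cur,
            suitable_future=suit_fut,
            percent_change=percent_change(suit_cur, suit_fut) if suit_cur > 0 else np.nan,
        )
        totals.append(rec)
    # global row: union of the (disjoint) regions
    g_cur = sum(t["suitable_current"] for t in totals)
    g_fut = sum(t["suitable_future"] for t in totals)
    totals.append(
        {
            "region": "global",
            "suitable_current": g_cur,
            "suitable_future": g_fut,
            "percent_change": percent_change(g_cur, g_fut) if g_cur > 0 else np.nan,
        }
    )
    return AreaReport(
        per_class=pd.DataFrame(rows), totals=pd.DataFrame(totals), min_class=min_class
    )


def area_report_from_totals(pairs: dict[str, tuple[float, float]], decimals: int = 1) -> pd.DataFrame:
    """Percent changes from (current, future) suitable-area totals.

    Convenience for re-deriving published change percentages from tabulated
    area pairs (any consistent unit).  Rounded to ``decimals`` places.
    """
    rows = [
        {
            "region": name,
            "suitable_current": cur,
            "suitable_future": fut,
            "percent_change": round(percent_change(cur, fut), decimals),
        }
        for name, (cur, fut) in pairs.items()
    ]
    return pd.DataFrame(rows)
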