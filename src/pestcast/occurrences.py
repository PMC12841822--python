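"""Occurrence records: ingestion, de-duplication, spatial rarefaction,
pseudo-absence generation.

Presence records (e.g. GBIF exports) arrive as lon/lat tables; duplicates at
identical coordinates are collapsed, spatial rarefaction thins records to a
minimum great-circle separation to reduce sampling bias, and the negative
class for the correlative model is a set of pseudo-absence points drawn
uniformly over valid cells away from every presence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "OccurrenceSet",
    "read_occurrences",
    "dedupe",
    "rarefy",
    "generate_pseudo_absences",
    "haversine_km",
]


@dataclass
class OccurrenceSet:
    """Coordinates labelled presence / pseudo_absence, with provenance ids."""

    lon: np.ndarray
    lat: np.ndarray
    label: np.ndarray = field(default=None)  # type: ignore[assignment]
    source_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lon = np.atleast_1d(np.asarray(self.lon, dtype=float))
        self.lat = np.atleast_1d(np.asarray(self.lat, dtype=float))
        n = self.lon.size
        if self.label is None:
            self.label = np.array(["presence"] * n, dtype=object)
        else:
            self.label = np.atleast_1d(np.asarray(self.label, dtype=object))
        if self.source_id is None:
            self.source_id = np.array([str(i) for i in range(n)], dtype=object)
        else:
            self.source_id = np.atleast_1d(np.asarray(self.source_id, dtype=object))
        if not (self.lat.size == self.label.size == self.source_id.size == n):
            raise ValueError("occurrence columns must have equal length")
        bad = np.flatnonzero(
            (self.lon < -180) | (self.lon >= 180) | (self.lat < -90) | (self.lat > 90)
        )
        if bad.size:
            i = bad[0]
            raise ValueError(
                f"record {self.source_id[i]} has out-of-range coordinates "
                f"(lon={self.lon[i]}, lat={self.lat[i]})"
            )

    def __len__(self) -> int:
        return self.lon.size

    @property
    def presences(self) -> "OccurrenceSet":
        return self.subset(self.label == "presence")

    def subset(self, mask: np.ndarray) -> "OccurrenceSet":
        return OccurrenceSet(self.lon[mask], self.lat[mask], self.label[mask], self.source_id[mask])

    def concat(self, other: "OccurrenceSet") -> "OccurrenceSet":
        return OccurrenceSet(
            np.concatenate([self.lon, other.lon]),
            np.concatenate([self.lat, other.lat]),
            np.concatenate([self.label, other.label]),
            np.concatenate([self.source_id, other.source_id]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lon": self.lon, "lat": self.lat, "label": self.label, "source_id": self.source_id}
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_occurrences(path) -> OccurrenceSet:
    """Read an occurrence CSV; a presence-only table (no label column) is
    accepted with every record labelled presence."""
    df = pd.read_csv(path, float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    for required in ("lon", "lat"):
        if required not in cols:
            raise ValueError(f"occurrence table lacks a {required!r} column")
    label = df[cols["label"]].to_numpy(dtype=object) if "label" in cols else None
    source = df[cols["source_id"]].astype(str).to_numpy(dtype=object) if "source_id" in cols else None
    return OccurrenceSet(df[cols["lon"]].to_numpy(float), df[cols["lat"]].to_numpy(float), label, source)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance on a 6371 km sphere; broadcasts over arrays."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def dedupe(points: OccurrenceSet, decimals: int = 4) -> OccurrenceSet:
    """Drop exact coordinate duplicates after rounding to 1e-4 degree.

    The first record of each (lon, lat, label) group is kept; input order is
    preserved.
    """
    key = list(
        zip(
            np.round(points.lon, decimals),
            np.round(points.lat, decimals),
            points.label,
        )
    )
    seen: set = set()
    keep = np.zeros(len(points), dtype=bool)
    for i, k in enumerate(key):
        if k not in seen:
            seen.add(k)
            keep[i] = True
    return points.subset(keep)


def rarefy(points: OccurrenceSet, min_distance_km: float) -> OccurrenceSet:
    """Greedy spatial thinning in input order.

    A point is kept iff it lies at least ``min_distance_km`` (great-circle)
    from every previously kept point; the result is therefore order-dependent
    and idempotent under re-application.
    """
    if min_distance_km < 0:
        raise ValueError("min_distance_km must be non-negative")
    if min_distance_km == 0 or len(points) == 0:
        return points.subset(np.ones(len(points), dtype=bool))
    keep_idx: list[int] = []
    for i in range(len(points)):
        if not keep_idx:
            keep_idx.append(i)
            continue
        d = haversine_km(
            points.lon[i], points.lat[i], points.lon[keep_idx], points.lat[keep_idx]
        )
        if np.all(d >= min_distance_km):
            keep_idx.append(i)
    mask = np.zeros(len(points), dtype=bool)
    mask[keep_idx] = True
    return points.subset(mask)


def generate_pseudo_absences(
    lat_axis: np.ndarray,
    lon_axis: np.ndarray,
    valid: np.ndarray,
    presences: OccurrenceSet,
    n: int,
    buffer_km: float = 50.0,
    seed: int = 0,
) -> OccurrenceSet:
    """Draw ``n`` pseudo-absence points uniformly over valid cells.

    Each point is placed uniformly within a uniformly chosen valid cell and
    must lie at least ``buffer_km`` from every presence.  Rejection sampling
    with a budget of 10000·n draws; deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    vi, vj = np.nonzero(valid)
    if vi.size == 0:
        raise ValueError("no valid cells in extent")
    dlat = float(lat_axis[1] - lat_axis[0]) if lat_axis.size > 1 else 1.0
    dlon = float(lon_axis[1] - lon_axis[0]) if lon_axis.size > 1 else 1.0
    out_lon: list[float] = []
    out_lat: list[float] = []
    budget = 10000 * n
    while len(out_lon) < n and budget > 0:
        budget -= 1
        k = rng.integers(vi.size)
        lat = lat_axis[vi[k]] + (rng.random() - 0.5) * dlat
        lon = lon_axis[vj[k]] + (rng.random() - 0.5) * dlon
        lat = float(np.clip(lat, -90.0, 90.0))
        if len(presences) and np.any(
            haversine_km(lon, lat, presences.lon, presences.lat) < buffer_km
        ):
            continue
        out_lon.append(lon)
        out_lat.append(lat)
    if len(out_lon) < n:
        raise RuntimeError(
            f"could not place {n} pseudo-absences with buffer {buffer_km} km "
            f"within the draw budget"
        )
    labels = np.array(["pseudo_absence"] * n, dtype=object)
    ids = np.array([f"pa{i}" for i in range(n)], dtype=object)
    return OccurrenceSet(np.array(out_lon), np.array(out_lat), labels, ids)
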