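"""Centroid geometry: distances, displacement statistics and catchment areas.

Distances are great-circle (haversine) on a sphere; at the tens-of-kilometre
scale of intermunicipal patient displacement the sub-kilometre error against
an ellipsoid is immaterial, and centroid-to-centroid distance is itself only
a proxy for real travel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import UnitTable, ValidationError
from .od import ODMatrix

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def haversine_km(
    a: tuple[float, float],
    b: tuple[float, float],
    radius_km: float = EARTH_RADIUS_KM,
) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    for lat, lon in (a, b):
        if not (-90 <= lat <= 90) or not (-180 <= lon <= 180):
            raise ValidationError(f"invalid coordinates: ({lat}, {lon})")
    lat1, lon1, lat2, lon2 = map(np.radians, (a[0], a[1], b[0], b[1]))
    h = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def distance_matrix_km(
    units: UnitTable, radius_km: float = EARTH_RADIUS_KM
) -> pd.DataFrame:
    """All-pairs haversine distances between unit centroids (km)."""
    lat = np.radians(units.frame["lat"].to_numpy())
    lon = np.radians(units.frame["lon"].to_numpy())
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    ids = units.unit_ids
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Displacement statistics
# ---------------------------------------------------------------------------


@dataclass
class DisplacementStats:
    """Patient-weighted mean displacement for cross-border flows.

    ``hub_mean_km`` averages over flows whose destination is the hub;
    ``other_mean_km`` over all remaining cross-border flows.  A mean is
    ``None`` (flagged undefined) when no such flow exists.
    """

    hub: str
    hub_mean_km: float | None
    other_mean_km: float | None
    hub_patients: int
    other_patients: int


def displacement_stats(
    od: ODMatrix,
    units: UnitTable,
    hub: str,
    radius_km: float = EARTH_RADIUS_KM,
) -> DisplacementStats:
    """Mean displacement into the hub vs into every other destination.

    Only cross-border entries (origin != destination) contribute; self-flows
    involve no displacement and are excluded.  Means are weighted by patient
    counts.
    """
    if hub not in od.counts.index:
        raise ValidationError(f"hub {hub!r} not in OD matrix")
    dist = distance_matrix_km(units, radius_km).reindex(
        index=od.counts.index, columns=od.counts.columns
    )
    counts = od.counts.to_numpy(dtype=float)
    d = dist.to_numpy()
    off = ~np.eye(len(counts), dtype=bool)
    hub_col = np.array([c == hub for c in od.counts.columns])
    hub_mask = off & hub_col[None, :]
    other_mask = off & ~hub_col[None, :]

    def _mean(mask: np.ndarray) -> tuple[float | None, int]:
        w = counts[mask]
        n = int(w.sum())
        if n == 0:
            return None, 0
        return float((w * d[mask]).sum() / n), n

    hub_mean, hub_n = _mean(hub_mask)
    other_mean, other_n = _mean(other_mask)
    return DisplacementStats(hub, hub_mean, other_mean, hub_n, other_n)


def expected_births(units: UnitTable, regional_birth_rate: float) -> pd.Series:
    """Expected annual births per unit: population x regional birth rate."""
    if regional_birth_rate <= 0:
        raise ValidationError("birth rate must be positive")
    return units.frame["population"] * regional_birth_rate


# ---------------------------------------------------------------------------
# Catchment areas
# ---------------------------------------------------------------------------


@dataclass
class CatchmentMap:
    """Origins supplying a destination, by migration intensity quartile.

    ``table`` has one row per origin with positive flow to the destination:
    columns ``intensity`` (share of the origin's cases going there, in
    (0, 1]) and ``quartile`` (Q1 lowest .. Q4 highest).
    """

    destination: str
    table: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=True)

    def to_geojson(self, units: UnitTable, path: str | Path) -> None:
        """Point features at origin centroids with intensity and quartile."""
        features = []
        for origin, row in self.table.iterrows():
            u = units.frame.loc[origin]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [float(u["lon"]), float(u["lat"])],
                    },
                    "properties": {
                        "origin": origin,
                        "destination": self.destination,
                        "intensity": float(row["intensity"]),
                        "quartile": row["quartile"],
                    },
                }
            )
        payload = {"type": "FeatureCollection", "features": features}
        Path(path).write_text(json.dumps(payload, indent=2))


def catchment_quartiles(od: ODMatrix, destination: str) -> CatchmentMap:
    """Classify a destination's catchment origins by intensity quartile.

    Intensity for origin *i* is the share of *i*'s cases hospitalized at the
    destination.  Quartile boundaries are the 25/50/75 percentiles (linear
    interpolation) of the destination's own intensity distribution; values
    on a boundary fall in the lower quartile.
    """
    if destination not in od.counts.columns:
        raise ValidationError(f"destination {destination!r} not in OD matrix")
    col = od.counts[destination]
    if col.sum() == 0:
        raise ValidationError(f"destination {destination!r} has zero in-flow")
    row_totals = od.counts.sum(axis=1)
    mask = col > 0
    intensity = (col[mask] / row_totals[mask]).astype(float)
    q25, q50, q75 = np.percentile(intensity.to_numpy(), [25, 50, 75])

    def label(x: float) -> str:
        if x <= q25:
            return "Q1"
        if x <= q50:
            return "Q2"
        if x <= q75:
            return "Q3"
        return "Q4"

    table = pd.DataFrame(
        {"intensity": intensity, "quartile": [label(x) for x in intensity]}
    )
    table.index.name = "origin"
    return CatchmentMap(destination=destination, table=table)
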