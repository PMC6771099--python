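"""Gravity-model synthetic generator for patient-flow studies.

Real hospitalization registries of this kind are administrative databases
that cannot be redistributed, so the generator emulates the statistical
structure the analysis relies on:

* a universe of ~60 municipalities of which ~26 form a designated health
  region around one dominant hub that concentrates ~75% of the designated
  region's beds for ~52% of its population;
* case volumes driven by a birth rate (pregnancy/childbirth/puerperium
  episodes slightly exceed births);
* destination choice by a gravity model — attraction grows with hospital
  capacity and decays exponentially with centroid distance, with
  multiplicative preferences for staying in town and for the hub.

Each origin draws its destinations from its own deterministic random
substream, so adding or removing units does not perturb the draws of the
remaining origins.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geo import distance_matrix_km
from .io import AdmissionRecord, UnitTable, ValidationError, _load_config_mapping


@dataclass
class SyntheticScenario:
    """Parameters of a synthetic patient-flow universe.

    The defaults describe a hub-dominated regional system: 60 functional
    units, 26 designated ones split into 3 micro-regions, hub holding 75%
    of designated beds and 52% of designated population, birth rate 15 per
    1000 inhabitants with 1.1 hospitalization episodes per birth.  The
    gravity parameters (``attraction_exponent``, ``decay_scale_km``,
    ``local_preference``, ``hub_preference``) shape destination choice;
    the defaults yield roughly a quarter of designated residents admitted
    outside their home municipality.
    """

    n_units: int = 60
    n_designated: int = 26
    n_micro_regions: int = 3
    hub_unit: str = "U001"
    hub_bed_share: float = 0.75
    hub_population_share: float = 0.52
    population_range: tuple[float, float] = (2_000.0, 80_000.0)
    birth_rate: float = 0.015
    episodes_per_birth: float = 1.1
    attraction_exponent: float = 1.0  # gamma: beds^gamma
    decay_scale_km: float = 30.0  # delta: exp(-d/delta)
    local_preference: float = 25.0  # lambda: multiplier for j = i
    hub_preference: float = 2.0  # eta: multiplier for j = hub
    hospital_unit_fraction: float = 0.35
    beds_per_thousand: float = 2.5
    bounding_box: tuple[float, float, float, float] = (-22.0, -20.2, -48.8, -47.0)
    year: int = 2012
    diagnosis_group: str = "XV"
    seed: int = 13

    def __post_init__(self) -> None:
        if not 0 < self.hub_bed_share <= 1:
            raise ValidationError("hub_bed_share must be in (0, 1]")
        if not 0 < self.hub_population_share < 1:
            raise ValidationError("hub_population_share must be in (0, 1)")
        if self.decay_scale_km <= 0:
            raise ValidationError("decay_scale_km must be positive")
        if self.local_preference < 1 or self.hub_preference < 1:
            raise ValidationError("preference multipliers must be >= 1")
        if self.n_designated > self.n_units:
            raise ValidationError("n_designated cannot exceed n_units")
        if self.episodes_per_birth < 1:
            raise ValidationError("episodes_per_birth must be >= 1")
        lo, hi = self.population_range
        if not 0 < lo <= hi:
            raise ValidationError("population_range must be 0 < min <= max")

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticScenario":
        data = _load_config_mapping(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown scenario key(s): {', '.join(sorted(unknown))}")
        for key in ("population_range", "bounding_box"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _substream(seed: int, label: str, key: str = "") -> np.random.Generator:
    """Deterministic per-purpose RNG stream derived from the global seed."""
    entropy = [seed, zlib.crc32(label.encode())]
    if key:
        entropy.append(zlib.crc32(key.encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def generate_units(scenario: SyntheticScenario) -> UnitTable:
    """Sample the unit universe: geography, population, beds, memberships.

    Centroids are uniform in the bounding box with the hub at its centre;
    populations log-uniform in ``population_range`` except the hub, whose
    population is set so it holds ``hub_population_share`` of the designated
    region.  Hospitals (beds > 0) go to the hub and the most populous other
    units; non-hub hospitals get beds proportional to population while the
    hub receives ``hub_bed_share`` of all designated-region beds.  The
    ``n_designated`` units nearest the hub form the designated region,
    partitioned into micro-regions by angular sector around the hub.
    """
    s = scenario
    ids = [f"U{i:03d}" for i in range(1, s.n_units + 1)]
    if s.hub_unit not in ids:
        raise ValidationError(f"hub_unit {s.hub_unit!r} outside generated id range")
    rng = _substream(s.seed, "geometry")
    lat_lo, lat_hi, lon_lo, lon_hi = s.bounding_box
    lat = rng.uniform(lat_lo, lat_hi, size=s.n_units)
    lon = rng.uniform(lon_lo, lon_hi, size=s.n_units)
    hub_idx = ids.index(s.hub_unit)
    lat[hub_idx] = (lat_lo + lat_hi) / 2
    lon[hub_idx] = (lon_lo + lon_hi) / 2

    lo, hi = s.population_range
    pop = np.exp(rng.uniform(np.log(lo), np.log(hi), size=s.n_units))
    pop = np.round(pop).astype(int)

    frame = pd.DataFrame(
        {
            "unit_id": ids,
            "name": [f"Town {i}" for i in ids],
            "lat": lat,
            "lon": lon,
            "population": pop,
            "beds": 0,
            "designated_region": "",
            "micro_region": "",
        }
    ).set_index("unit_id")

    # designated region: hub + nearest neighbours
    dist = distance_matrix_km(UnitTable(frame.reset_index()))
    order = dist[s.hub_unit].sort_values(kind="stable").index.tolist()
    designated = order[: s.n_designated]  # hub first (distance 0)
    frame.loc[designated, "designated_region"] = "R1"

    # hub population fixed by its designated-region share
    others_designated = [u for u in designated if u != s.hub_unit]
    others_pop = int(frame.loc[others_designated, "population"].sum())
    share = s.hub_population_share
    frame.at[s.hub_unit, "population"] = int(round(share / (1 - share) * others_pop))

    # hospitals at the hub and the most populous remaining units
    n_hosp = max(1, round(s.hospital_unit_fraction * s.n_units))
    non_hub = frame.drop(index=s.hub_unit)
    ranked = non_hub.sort_values(["population", "name"], ascending=[False, True])
    hosp_units = list(ranked.index[: max(0, n_hosp - 1)])
    if s.hub_bed_share < 1.0:
        beds = np.round(
            s.beds_per_thousand / 1000.0 * frame.loc[hosp_units, "population"]
        ).astype(int)
        frame.loc[hosp_units, "beds"] = np.maximum(beds, 1)
        designated_beds = int(frame.loc[others_designated, "beds"].sum())
        hub_beds = int(round(s.hub_bed_share / (1 - s.hub_bed_share) * designated_beds))
        frame.at[s.hub_unit, "beds"] = max(hub_beds, 1)
    else:
        frame.at[s.hub_unit, "beds"] = max(
            1, int(round(s.beds_per_thousand / 1000.0 * frame.at[s.hub_unit, "population"]))
        )

    # micro-regions: angular sectors around the hub (hub joins sector 1)
    desig = frame.loc[designated]
    ang = np.arctan2(
        desig["lat"] - frame.at[s.hub_unit, "lat"],
        desig["lon"] - frame.at[s.hub_unit, "lon"],
    )
    sector = np.floor((ang + np.pi) / (2 * np.pi) * s.n_micro_regions).astype(int)
    sector = np.clip(sector, 0, s.n_micro_regions - 1)
    frame.loc[designated, "micro_region"] = [f"M{k + 1}" for k in sector]
    frame.at[s.hub_unit, "micro_region"] = "M1"
    return UnitTable(frame.reset_index())


def gravity_probabilities(
    scenario: SyntheticScenario, units: UnitTable
) -> pd.DataFrame:
    """Per-origin destination-choice distribution over hospital units.

    Unnormalized weight for origin *i*, destination *j* (beds_j > 0):

        u_ij = beds_j**gamma * exp(-d_ij / delta) * lambda**[j == i] * eta**[j == hub]

    with d_ij the haversine centroid distance.  Rows sum to 1.
    """
    s = scenario
    beds = units.frame["beds"]
    dest = beds.index[beds > 0].tolist()
    if not dest:
        raise ValidationError("no unit has hospital beds; no destinations exist")
    d = distance_matrix_km(units).loc[:, dest]
    w = (beds[dest].to_numpy() ** s.attraction_exponent) * np.exp(
        -d.to_numpy() / s.decay_scale_km
    )
    w = pd.DataFrame(w, index=units.unit_ids, columns=dest)
    for j in dest:
        if j in w.index:
            w.at[j, j] *= s.local_preference
    if s.hub_unit in w.columns:
        w[s.hub_unit] *= s.hub_preference
    return w.div(w.sum(axis=1), axis=0)


def generate_admissions(
    scenario: SyntheticScenario, units: UnitTable
) -> list[AdmissionRecord]:
    """Draw hospitalization records origin by origin.

    Per origin the case count is ``round(population * birth_rate *
    episodes_per_birth)`` and destinations are drawn multinomially from the
    gravity distribution, using a per-origin substream of the scenario
    seed.
    """
    s = scenario
    probs = gravity_probabilities(scenario, units)
    records: list[AdmissionRecord] = []
    for origin in units.unit_ids:
        population = int(units.frame.at[origin, "population"])
        n_cases = int(round(population * s.birth_rate * s.episodes_per_birth))
        if n_cases == 0:
            continue
        rng = _substream(s.seed, "admissions", origin)
        counts = rng.multinomial(n_cases, probs.loc[origin].to_numpy())
        for dest, c in zip(probs.columns, counts):
            records.extend(
                AdmissionRecord(origin, dest, s.diagnosis_group, s.year)
                for _ in range(int(c))
            )
    return records


# ---------------------------------------------------------------------------
# Preset scenarios
# ---------------------------------------------------------------------------


def drs13_like(seed: int = 13) -> SyntheticScenario:
    """The default hub-dominated regional scenario (all defaults)."""
    return SyntheticScenario(seed=seed)


def toy3_units() -> UnitTable:
    """Three-unit worked example: A (some outflow), B (attractor), C.

    Flows are fixed rather than sampled — see :func:`toy3_records` — so
    every downstream quantity can be checked by hand.
    """
    frame = pd.DataFrame(
        {
            "unit_id": ["A", "B", "C"],
            "name": ["Alfa", "Bravo", "Carlos"],
            "lat": [-21.00, -21.10, -21.30],
            "lon": [-47.90, -47.80, -47.70],
            "population": [10_000, 5_000, 4_000],
            "beds": [20, 80, 10],
            "designated_region": ["R1", "R1", "R1"],
            "micro_region": ["M1", "M1", "M1"],
        }
    )
    return UnitTable(frame)


_TOY3_FLOWS = [("A", "A", 66), ("A", "B", 34), ("B", "B", 50), ("C", "B", 10), ("C", "C", 40)]


def toy3_records(year: int = 2012) -> list[AdmissionRecord]:
    """200 deterministic records realizing the toy3 flow pattern."""
    records = []
    for origin, dest, n in _TOY3_FLOWS:
        records.extend(AdmissionRecord(origin, dest, "XV", year) for _ in range(n))
    return records
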