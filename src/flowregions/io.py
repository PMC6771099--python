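"""Domain types and CSV input/output for hospitalization flow studies.

The analysis consumes two tables:

* **admissions** — one row per hospitalization episode, carrying the
  patient's municipality of residence, the municipality of the hospital,
  a diagnosis-group code (e.g. the ICD-10 chapter label ``"XV"`` for
  pregnancy, childbirth and the puerperium) and the calendar year;
* **units** — one row per geographic unit (municipality), with a centroid,
  population, hospital bed count and optional designated-region /
  micro-region membership.

Both are plain UTF-8 comma-separated files with a mandatory header row.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

log = logging.getLogger("flowregions")

ADMISSION_COLUMNS = ["residence_unit", "hospital_unit", "diagnosis_group", "year"]
UNIT_COLUMNS = [
    "unit_id",
    "name",
    "lat",
    "lon",
    "population",
    "beds",
    "designated_region",
    "micro_region",
]


class FormatError(ValueError):
    """A file does not conform to the expected CSV layout."""


class ValidationError(ValueError):
    """Data violates a dataset invariant (ranges, uniqueness, unknown ids)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdmissionRecord:
    """One hospitalization: who (by residence), where, for what, when."""

    residence_unit: str
    hospital_unit: str
    diagnosis_group: str
    year: int

    def __post_init__(self) -> None:
        if not self.residence_unit:
            raise ValidationError("residence_unit must be non-empty")
        if not self.hospital_unit:
            raise ValidationError("hospital_unit must be non-empty")
        if self.year <= 0:
            raise ValidationError(f"year must be positive, got {self.year}")


class UnitTable:
    """Per-unit attributes: centroid, population, beds, region membership.

    Thin wrapper around a :class:`pandas.DataFrame` indexed by ``unit_id``;
    construction validates uniqueness, coordinate ranges and non-negative
    counts.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.name != "unit_id":
            if "unit_id" not in frame.columns:
                raise FormatError("unit table requires a unit_id column")
            frame = frame.set_index("unit_id")
        frame.index = frame.index.astype(str)
        missing = [c for c in UNIT_COLUMNS[1:] if c not in frame.columns]
        if missing:
            raise FormatError(f"unit table missing column(s): {', '.join(missing)}")
        if frame.index.has_duplicates:
            dupes = sorted(frame.index[frame.index.duplicated()].unique())
            raise ValidationError(f"duplicate unit_id(s): {', '.join(dupes)}")
        for col in ("lat", "lon"):
            frame[col] = pd.to_numeric(frame[col])
        for col in ("population", "beds"):
            frame[col] = pd.to_numeric(frame[col]).astype(int)
        if ((frame["lat"] < -90) | (frame["lat"] > 90)).any():
            bad = frame.index[(frame["lat"] < -90) | (frame["lat"] > 90)].tolist()
            raise ValidationError(f"latitude out of [-90, 90] for unit(s): {bad}")
        if ((frame["lon"] < -180) | (frame["lon"] > 180)).any():
            bad = frame.index[(frame["lon"] < -180) | (frame["lon"] > 180)].tolist()
            raise ValidationError(f"longitude out of [-180, 180] for unit(s): {bad}")
        if (frame["population"] < 0).any():
            raise ValidationError("population must be >= 0")
        if (frame["beds"] < 0).any():
            raise ValidationError("beds must be >= 0")
        frame["designated_region"] = frame["designated_region"].fillna("").astype(str)
        frame["micro_region"] = frame["micro_region"].fillna("").astype(str)
        self.frame = frame

    # -- accessors ----------------------------------------------------------

    @property
    def unit_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, unit_id: str) -> bool:
        return unit_id in self.frame.index

    @property
    def designated_units(self) -> set[str]:
        """Units belonging to a designated (legal/administrative) region."""
        return set(self.frame.index[self.frame["designated_region"] != ""])

    @property
    def hospital_units(self) -> set[str]:
        """Units with at least one hospital bed (valid destinations)."""
        return set(self.frame.index[self.frame["beds"] > 0])

    def micro_region_members(self) -> dict[str, set[str]]:
        """Mapping micro-region id -> set of member unit ids."""
        sub = self.frame[self.frame["micro_region"] != ""]
        return {
            str(mr): set(group.index)
            for mr, group in sub.groupby("micro_region", sort=True)
        }

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "UnitTable":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        frame = pd.read_csv(path, dtype={"unit_id": str}, keep_default_na=False,
                            na_values=[""])
        return cls(frame)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=True)


@dataclass
class StudyConfig:
    """Tunable parameters of a flow study.

    ``min_sent_patients`` is a *strict* lower bound: an origin qualifies only
    when it sends strictly more than this many patients into the study
    hospitals (default 5).  ``sufficiency_threshold`` is the paired LIFO/LOFI
    criterion, in percent, also applied strictly (default 75).
    """

    diagnosis_filter: str = "XV"
    year_filter: int | None = None
    min_sent_patients: int = 5
    sufficiency_threshold: float = 75.0
    earth_radius_km: float = 6371.0088
    random_seed: int = 0
    unknown_unit_mode: str = "strict"  # "strict" | "lenient"
    origin_filter_mode: str = "origin"  # "origin" | "per_edge"
    enlargement_rank: str = "exchange"  # "exchange" | "inflow" | "distance"

    def __post_init__(self) -> None:
        if self.min_sent_patients < 0:
            raise ValidationError("min_sent_patients must be >= 0")
        if not 0 < self.sufficiency_threshold < 100:
            raise ValidationError("sufficiency_threshold must be in (0, 100)")
        if self.unknown_unit_mode not in ("strict", "lenient"):
            raise ValidationError("unknown_unit_mode must be 'strict' or 'lenient'")

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        data = _load_config_mapping(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_config_mapping(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise FormatError(f"config file {path} must contain a mapping")
    return data


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_admissions(path: str | Path, config: StudyConfig) -> list[AdmissionRecord]:
    """Read an admissions CSV and apply the study's diagnosis/year filter.

    Raises :class:`FormatError` naming the missing column if the header is
    incomplete, and :class:`FormatError` with the (1-based data) row number
    for an unparseable row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ADMISSION_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"admissions file missing column: {col}")
    records: list[AdmissionRecord] = []
    kept = 0
    for pos, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            rec = AdmissionRecord(
                residence_unit=str(row.residence_unit),
                hospital_unit=str(row.hospital_unit),
                diagnosis_group=str(row.diagnosis_group),
                year=int(row.year),
            )
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"admissions row {pos}: {exc}") from exc
        if rec.diagnosis_group != config.diagnosis_filter:
            continue
        if config.year_filter is not None and rec.year != config.year_filter:
            continue
        kept += 1
        records.append(rec)
    log.info(
        "read_admissions: %d rows read, %d kept after filter (diagnosis=%s, year=%s)",
        len(frame), kept, config.diagnosis_filter, config.year_filter,
    )
    return records


def write_admissions(records: Iterable[AdmissionRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [dataclasses.asdict(r) for r in records], columns=ADMISSION_COLUMNS
    )
    frame.to_csv(path, index=False)


def read_units(path: str | Path) -> UnitTable:
    """Read and validate a unit-attribute CSV."""
    return UnitTable.from_csv(path)


# ---------------------------------------------------------------------------
# Dataset validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Cross-check of admission records against the unit table."""

    n_records: int
    unknown_unit_issues: list[dict] = field(default_factory=list)
    inactive_units: list[str] = field(default_factory=list)
    n_dropped: int = 0
    mode: str = "strict"
    clean_records: list[AdmissionRecord] = field(default_factory=list, repr=False)

    @property
    def ok(self) -> bool:
        return not self.unknown_unit_issues or self.mode == "lenient"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_records": self.n_records,
            "n_dropped": self.n_dropped,
            "mode": self.mode,
            "unknown_unit_issues": self.unknown_unit_issues,
            "inactive_units": self.inactive_units,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def validate_dataset(
    records: Sequence[AdmissionRecord],
    units: UnitTable,
    mode: str = "strict",
) -> ValidationReport:
    """Check that every record refers to known units; list inactive units.

    In ``strict`` mode any record whose residence or hospital unit is absent
    from the unit table raises :class:`ValidationError`; in ``lenient`` mode
    such records are dropped (logged) and the cleaned sequence is returned in
    the report.
    """
    known = set(units.unit_ids)
    issues: list[dict] = []
    clean: list[AdmissionRecord] = []
    active: set[str] = set()
    for pos, rec in enumerate(records, start=1):
        bad = [u for u in (rec.residence_unit, rec.hospital_unit) if u not in known]
        if bad:
            issues.append({"record": pos, "unknown_units": bad})
        else:
            clean.append(rec)
        active.update((rec.residence_unit, rec.hospital_unit))
    inactive = sorted(known - active)
    if issues and mode == "strict":
        offending = sorted({u for iss in issues for u in iss["unknown_units"]})
        raise ValidationError(
            f"{len(issues)} record(s) reference unknown unit(s): {', '.join(offending)}"
        )
    if issues:
        log.warning("validate_dataset: dropped %d record(s) with unknown units", len(issues))
    return ValidationReport(
        n_records=len(records),
        unknown_unit_issues=issues,
        inactive_units=inactive,
        n_dropped=len(issues),
        mode=mode,
        clean_records=clean,
    )
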