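"""LIFO/LOFI sufficiency analysis of hospital service areas.

The Elzinga–Hogarty market-delineation coefficients, adapted to patient
flows:

* **LIFO** ("little in from outside") = 1 − inflow / hospitalizations inside
  the subject, in percent.  High when the subject's hospitals serve mostly
  their own residents.
* **LOFI** ("little out from inside") = 1 − outflow / resident cases, in
  percent.  High when residents rarely leave the subject for care.

A unit or unit set is *Sufficient* when both coefficients strictly exceed a
threshold (75% by default): it retains its own patients and is not
critically relied upon by its surroundings.  Set-level coefficients
aggregate flows before taking the ratio — a set is treated as a single
merged unit, so flows internal to the set are neither inflow nor outflow.

The successive-enlargement procedure (after Frech et al.) grows a candidate
region one unit at a time until the paired criterion is met, each step
annexing the external unit exchanging the most patients with the current
set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .io import UnitTable, ValidationError
from .od import ODMatrix

SUFFICIENT = "Sufficient"
INSUFFICIENT = "Insufficient"
UNDEFINED = "Undefined"


@dataclass
class SufficiencyResult:
    """LIFO/LOFI coefficients and sufficiency label for a unit or unit set."""

    subject: str
    level: str  # "municipality" | "micro-region" | "region" | "set"
    lifo_pct: float | None
    lofi_pct: float | None
    label: str
    threshold_pct: float
    members: frozenset[str] = field(default_factory=frozenset)

    @property
    def lifo_rounded(self) -> int | None:
        return None if self.lifo_pct is None else round(self.lifo_pct)

    @property
    def lofi_rounded(self) -> int | None:
        return None if self.lofi_pct is None else round(self.lofi_pct)


def lifo_lofi(
    od: ODMatrix, subject: Iterable[str]
) -> tuple[float | None, float | None]:
    """Paired LIFO/LOFI percentages for a unit set treated as one aggregate.

    LIFO = (1 − inflow/H) × 100 with H the hospitalizations occurring inside
    the subject and inflow the part originating outside; undefined (None)
    when H = 0.  LOFI = (1 − outflow/R) × 100 with R the subject residents'
    cases and outflow the part hospitalized outside; undefined when R = 0.
    """
    subject = set(subject)
    if not subject:
        raise ValidationError("subject must be non-empty")
    unknown = subject - set(od.unit_ids)
    if unknown:
        raise ValidationError(f"subject contains unknown unit(s): {sorted(unknown)}")
    inside = [u for u in od.unit_ids if u in subject]
    outside = [u for u in od.unit_ids if u not in subject]

    hospitalized = int(od.counts.loc[:, inside].to_numpy().sum())
    inflow = int(od.counts.loc[outside, inside].to_numpy().sum())
    residents = int(od.counts.loc[inside, :].to_numpy().sum())
    outflow = int(od.counts.loc[inside, outside].to_numpy().sum())

    lifo = None if hospitalized == 0 else (1 - inflow / hospitalized) * 100.0
    lofi = None if residents == 0 else (1 - outflow / residents) * 100.0
    return lifo, lofi


def classify_sufficiency(
    lifo_pct: float | None, lofi_pct: float | None, threshold_pct: float = 75.0
) -> str:
    """Label a LIFO/LOFI pair: Sufficient iff both strictly exceed threshold.

    The comparison uses unrounded percentages; reports may print rounded
    values equal to the threshold for a subject that is nevertheless above
    it.  Any undefined coefficient yields the Undefined label — a subject
    with no hospital activity cannot be sufficient.
    """
    if not 0 < threshold_pct < 100:
        raise ValidationError("threshold_pct must be in (0, 100)")
    if lifo_pct is None or lofi_pct is None:
        return UNDEFINED
    if lifo_pct > threshold_pct and lofi_pct > threshold_pct:
        return SUFFICIENT
    return INSUFFICIENT


def _result(
    od: ODMatrix,
    subject_ids: set[str],
    name: str,
    level: str,
    threshold_pct: float,
) -> SufficiencyResult:
    lifo, lofi = lifo_lofi(od, subject_ids)
    return SufficiencyResult(
        subject=name,
        level=level,
        lifo_pct=lifo,
        lofi_pct=lofi,
        label=classify_sufficiency(lifo, lofi, threshold_pct),
        threshold_pct=threshold_pct,
        members=frozenset(subject_ids),
    )


def sufficiency_table(
    od: ODMatrix, units: UnitTable, threshold_pct: float = 75.0
) -> list[SufficiencyResult]:
    """The municipal / micro-region / region sufficiency hierarchy.

    One row per unit *with hospitalization* (column sum > 0), one aggregate
    row per micro-region, and one for the whole designated region (all units
    if no designated region is marked).
    """
    results: list[SufficiencyResult] = []
    col_sums = od.counts.sum(axis=0)
    for unit in od.unit_ids:
        if col_sums[unit] > 0:
            results.append(_result(od, {unit}, unit, "municipality", threshold_pct))
    for micro, members in sorted(units.micro_region_members().items()):
        members = members & set(od.unit_ids)
        if members:
            results.append(_result(od, members, micro, "micro-region", threshold_pct))
    designated = units.designated_units & set(od.unit_ids)
    region_ids = designated if designated else set(od.unit_ids)
    region_name = (
        sorted({units.frame.at[u, "designated_region"] for u in designated})[0]
        if designated
        else "all-units"
    )
    results.append(_result(od, region_ids, region_name, "region", threshold_pct))
    return results


def sufficiency_table_to_csv(results: list[SufficiencyResult], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "subject": [r.subject for r in results],
            "level": [r.level for r in results],
            "lifo_pct": [r.lifo_rounded for r in results],
            "lofi_pct": [r.lofi_rounded for r in results],
            "lifo_pct_exact": [r.lifo_pct for r in results],
            "lofi_pct_exact": [r.lofi_pct for r in results],
            "label": [r.label for r in results],
        }
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Successive enlargement
# ---------------------------------------------------------------------------


@dataclass
class EnlargementStep:
    """One evaluation in the enlargement trace."""

    added_unit: str | None  # None for the seed evaluation
    set_size: int
    lifo_pct: float | None
    lofi_pct: float | None
    label: str


@dataclass
class EnlargementResult:
    final_set: set[str]
    trace: list[EnlargementStep]

    @property
    def label(self) -> str:
        return self.trace[-1].label

    def to_json(self, path: str | Path) -> None:
        payload = {
            "final_set": sorted(self.final_set),
            "label": self.label,
            "trace": [
                {
                    "added_unit": s.added_unit,
                    "set_size": s.set_size,
                    "lifo_pct": s.lifo_pct,
                    "lofi_pct": s.lofi_pct,
                    "label": s.label,
                }
                for s in self.trace
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def frech_enlarge(
    od: ODMatrix,
    seed_set: Iterable[str],
    threshold_pct: float = 75.0,
    rank: str = "exchange",
    units: UnitTable | None = None,
) -> EnlargementResult:
    """Grow a candidate region until it satisfies the paired LIFO/LOFI test.

    Starting from ``seed_set``, repeatedly: evaluate the current set; stop
    if Sufficient; otherwise annex the external unit ranked highest by the
    chosen criterion — ``exchange`` (total patients exchanged with the set,
    in + out; the default), ``inflow`` (patients sent into the set) or
    ``distance`` (nearest centroid to the set, requires ``units``).  Ties
    break lexicographically by unit id.  Stops with an Insufficient (or
    Undefined) final set when no external unit has positive exchange.
    """
    current = set(seed_set)
    if not current:
        raise ValidationError("seed set must be non-empty")
    if rank == "distance" and units is None:
        raise ValidationError("distance ranking requires the unit table")
    all_ids = list(od.unit_ids)
    trace: list[EnlargementStep] = []
    added: str | None = None
    while True:
        lifo, lofi = lifo_lofi(od, current)
        label = classify_sufficiency(lifo, lofi, threshold_pct)
        trace.append(EnlargementStep(added, len(current), lifo, lofi, label))
        if label == SUFFICIENT or len(current) == len(all_ids):
            break
        inside = [u for u in all_ids if u in current]
        external = [u for u in all_ids if u not in current]
        into = od.counts.loc[external, inside].sum(axis=1)
        out_of = od.counts.loc[inside, external].sum(axis=0)
        exchange = into + out_of
        candidates = exchange[exchange > 0]
        if candidates.empty:
            break
        if rank == "exchange":
            score = candidates
        elif rank == "inflow":
            score = into[candidates.index]
        elif rank == "distance":
            from .geo import distance_matrix_km  # local import: avoids cycle

            dist = distance_matrix_km(units)
            # nearer units score higher
            score = -dist.loc[candidates.index, inside].min(axis=1)
        else:
            raise ValueError(f"unknown ranking: {rank!r}")
        best = min(score.index, key=lambda u: (-score[u], u))
        current.add(best)
        added = best
    return EnlargementResult(final_set=current, trace=trace)
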