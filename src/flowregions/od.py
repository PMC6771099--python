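"""Origin-destination matrices of patient flows.

The OD matrix aggregates hospitalization records into counts ``counts[i, j]``
= patients residing in unit *i* hospitalized in unit *j*.  Diagonal entries
are local (same-municipality) care; off-diagonal entries are cross-border
admissions.  The matrix is square over the full unit universe so that row
and column sums are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import AdmissionRecord, UnitTable, ValidationError

log = logging.getLogger("flowregions")


@dataclass
class ODMatrix:
    """Square origin x destination count matrix with filter provenance."""

    counts: pd.DataFrame  # index = origins, columns = destinations, int
    filter_applied: str = ""
    dropped_records: int = 0

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(self.counts.columns):
            raise ValidationError("OD matrix must be square on the same unit ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("OD matrix entries must be non-negative")

    @property
    def unit_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def total(self) -> int:
        """Grand total of counts = number of contributing records."""
        return int(self.counts.to_numpy().sum())

    @property
    def hospital_units(self) -> set[str]:
        """Destinations that actually received patients (column sum > 0)."""
        sums = self.counts.sum(axis=0)
        return set(sums.index[sums > 0])

    @property
    def off_diagonal_total(self) -> int:
        m = self.counts.to_numpy()
        return int(m.sum() - np.trace(m))

    # -- serialization ------------------------------------------------------

    def to_long_csv(self, path: str | Path) -> None:
        """Long format (origin, destination, count), non-zero entries only."""
        stacked = self.counts.stack()
        long = stacked[stacked > 0].rename("count").reset_index()
        long.columns = ["origin", "destination", "count"]
        long.to_csv(path, index=False)

    def to_square_csv(self, path: str | Path) -> None:
        self.counts.to_csv(path, index=True)


def build_od_matrix(
    records: Sequence[AdmissionRecord], units: UnitTable
) -> ODMatrix:
    """Aggregate records into an OD count matrix over the unit universe."""
    ids = units.unit_ids
    known = set(ids)
    for rec in records:
        if rec.residence_unit not in known or rec.hospital_unit not in known:
            raise ValidationError(
                f"record references unknown unit: "
                f"{rec.residence_unit!r} -> {rec.hospital_unit!r}"
            )
    counts = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    if records:
        pairs = pd.DataFrame(
            {
                "origin": [r.residence_unit for r in records],
                "destination": [r.hospital_unit for r in records],
            }
        )
        tab = pd.crosstab(pairs["origin"], pairs["destination"])
        counts.loc[tab.index, tab.columns] += tab.astype(int)
    return ODMatrix(counts=counts)


def apply_origin_filter(
    od: ODMatrix,
    hospital_set: set[str],
    min_sent: int,
    mode: str = "origin",
) -> ODMatrix:
    """Drop origins without significant flow into the study hospitals.

    In ``origin`` mode (default) an origin is retained when its *total* flow
    into ``hospital_set`` is strictly greater than ``min_sent``; otherwise
    its whole row is zeroed and the dropped records are counted.  In
    ``per_edge`` mode each origin->hospital edge is tested individually
    against the same strict threshold.  Members of ``hospital_set`` are
    always retained as origins.
    """
    unknown = hospital_set - set(od.unit_ids)
    if unknown:
        raise ValidationError(f"hospital_set contains unknown unit(s): {sorted(unknown)}")
    counts = od.counts.copy()
    hosp_cols = [u for u in od.unit_ids if u in hospital_set]
    if mode == "origin":
        sent = counts[hosp_cols].sum(axis=1)
        keep = (sent > min_sent) | counts.index.isin(hospital_set)
        dropped = int(counts.loc[~keep].to_numpy().sum())
        counts.loc[~keep] = 0
        removed = sorted(counts.index[~keep])
    elif mode == "per_edge":
        block = counts.loc[:, hosp_cols]
        small = (block <= min_sent) & (block > 0)
        for u in hosp_cols:  # self-flows are local care, never filtered
            if u in small.index:
                small.at[u, u] = False
        dropped = int(block.to_numpy()[small.to_numpy()].sum())
        counts.loc[:, hosp_cols] = block.where(~small, 0)
        removed = []
    else:
        raise ValueError(f"unknown filter mode: {mode!r}")
    if dropped:
        log.info("apply_origin_filter: dropped %d record(s) (mode=%s)", dropped, mode)
    desc = (
        f"{od.filter_applied}; " if od.filter_applied else ""
    ) + f"origins sending > {min_sent} patients into {len(hospital_set)} hospital units (mode={mode})"
    if mode == "origin" and removed:
        desc += f"; removed origins: {', '.join(removed)}"
    return ODMatrix(
        counts=counts,
        filter_applied=desc,
        dropped_records=od.dropped_records + dropped,
    )


def migration_intensity(od: ODMatrix) -> pd.DataFrame:
    """Per-origin destination shares: entry (i, j) = counts[i, j] / row total.

    Rows with zero total are undefined and returned as all-NaN (flagged, not
    raised); every defined row sums to 1.
    """
    totals = od.counts.sum(axis=1)
    intensity = od.counts.div(totals.where(totals > 0), axis=0).astype(float)
    undefined = sorted(totals.index[totals == 0])
    if undefined:
        log.info("migration_intensity: %d origin(s) with no cases (rows NaN)", len(undefined))
    return intensity


@dataclass
class CrossBorderSummary:
    """Hospitalization totals for a resident scope and its cross-border part."""

    total: int
    cross_border: int
    scope_size: int

    @property
    def proportion_pct(self) -> float:
        """Cross-border share of all hospitalizations, one-decimal percent."""
        if self.total == 0:
            return float("nan")
        return round(100.0 * self.cross_border / self.total, 1)


def cross_border_summary(od: ODMatrix, scope: Iterable[str]) -> CrossBorderSummary:
    """Count hospitalizations of scope residents and how many crossed a border.

    ``total`` sums the rows of scope residents; ``cross_border`` counts the
    off-diagonal part of those rows (residence differs from hospital
    municipality).
    """
    scope = set(scope)
    if not scope:
        raise ValidationError("scope must be non-empty")
    unknown = scope - set(od.unit_ids)
    if unknown:
        raise ValidationError(f"scope contains unknown unit(s): {sorted(unknown)}")
    rows = od.counts.loc[sorted(scope)]
    total = int(rows.to_numpy().sum())
    local = int(sum(od.counts.at[u, u] for u in scope))
    return CrossBorderSummary(total=total, cross_border=total - local, scope_size=len(scope))


def delineate_functional_region(
    od: ODMatrix, designated_hospitals: set[str], min_sent: int
) -> set[str]:
    """Data-derived functional region around a designated hospital set.

    The functional region is the designated units plus every origin sending
    strictly more than ``min_sent`` patients into the designated hospitals —
    the area actually served, as opposed to the legally drawn one.
    """
    unknown = designated_hospitals - set(od.unit_ids)
    if unknown:
        raise ValidationError(f"unknown designated unit(s): {sorted(unknown)}")
    cols = [u for u in od.unit_ids if u in designated_hospitals]
    sent = od.counts[cols].sum(axis=1)
    senders = set(sent.index[sent > min_sent])
    return set(designated_hospitals) | senders
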