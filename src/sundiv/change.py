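"""Composition-change and range-change indices between two censuses.

Two bespoke species-level indices for a zone:

* **%CC (percentage composition change)** — each species' percentage
  contribution to the zone total is computed at both censuses; the change is
  the difference of the contributions standardized by their sum, times 100.
  It runs from -100% (present, then absent: local extinction) to +100%
  (absent, then present: introduction) and is invariant to uniform rescaling
  of either census' counts.

* **Range-change index** — the change in the number of occupied plots,
  standardized by the total number of plots at which the species was present
  at either time (the union of the two occupied sets).  It runs from -1
  (local extinction) through 0 (identical occupancy) to +1 (introduction).

Species absent at both times have no defined change and are flagged rather
than reported as stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .census import CensusTable


class DegenerateInputError(ValueError):
    """Zero total abundance where a contribution is required."""


@dataclass
class CompositionChangeRecord:
    species: str
    zone: str
    count_start: int
    count_end: int
    contrib_start: float    # percent
    contrib_end: float      # percent
    cc: float | None        # percent, in [-100, 100]; None if absent both times

    @property
    def defined(self) -> bool:
        return self.cc is not None


@dataclass
class RangeChangeRecord:
    species: str
    zone: str
    n_start: int
    n_end: int
    denom: int
    index: float | None     # in [-1, 1]; None if absent both times

    @property
    def defined(self) -> bool:
        return self.index is not None


def percent_contribution(zone_counts: Mapping[str, int]) -> dict[str, float]:
    """Each species' percentage contribution to the zone total.

    Percentages are computed from unrounded ratios and sum to 100.
    """
    total = float(sum(zone_counts.values()))
    if total <= 0:
        raise DegenerateInputError("zone total count is zero")
    return {sp: 100.0 * c / total for sp, c in zone_counts.items()}


def percent_composition_change(
    start: Mapping[str, int],
    end: Mapping[str, int],
    zone: str = "",
    include_undefined: bool = False,
) -> list[CompositionChangeRecord]:
    """%CC per species between two censuses of one zone.

    The change is computed on unrounded contributions; rounding is left to
    presentation.  Species with zero counts at both times are undefined and
    excluded unless ``include_undefined``.
    """
    cs = percent_contribution(start)
    ce = percent_contribution(end)
    out = []
    for sp in list(dict.fromkeys([*start, *end])):
        a, b = cs.get(sp, 0.0), ce.get(sp, 0.0)
        if a + b == 0:
            if include_undefined:
                out.append(CompositionChangeRecord(
                    sp, zone, int(start.get(sp, 0)), int(end.get(sp, 0)), a, b, None
                ))
            continue
        cc = 100.0 * (b - a) / (b + a)
        out.append(CompositionChangeRecord(
            sp, zone, int(start.get(sp, 0)), int(end.get(sp, 0)), a, b, cc
        ))
    return out


def range_change_index(
    occupancy_start: Mapping[str, frozenset | set],
    occupancy_end: Mapping[str, frozenset | set],
    zone: str = "",
    denominator: str = "union",
    include_undefined: bool = False,
) -> list[RangeChangeRecord]:
    """Occupancy-based range expansion/contraction per species.

    ``denominator="union"`` (default) standardizes by the number of plots
    occupied at either time; ``"sum"`` by the summed occupancy counts.  Both
    attain the stated -1/0/+1 endpoints.
    """
    if denominator not in ("union", "sum"):
        raise ValueError("denominator must be 'union' or 'sum'")
    out = []
    for sp in list(dict.fromkeys([*occupancy_start, *occupancy_end])):
        s = set(occupancy_start.get(sp, set()))
        e = set(occupancy_end.get(sp, set()))
        if not s and not e:
            if include_undefined:
                out.append(RangeChangeRecord(sp, zone, 0, 0, 0, None))
            continue
        denom = len(s | e) if denominator == "union" else len(s) + len(e)
        out.append(RangeChangeRecord(
            sp, zone, len(s), len(e), denom, (len(e) - len(s)) / denom
        ))
    return out


def _zone_species_counts(table: CensusTable, zone: str, year: int) -> dict[str, int]:
    rec = table.records
    sub = rec.loc[(rec["zone"] == zone) & (rec["year"] == year)]
    return sub.groupby("species")["count"].sum().to_dict()


def _zone_occupancy(table: CensusTable, zone: str, year: int) -> dict[str, set]:
    rec = table.records
    sub = rec.loc[(rec["zone"] == zone) & (rec["year"] == year) & (rec["count"] > 0)]
    return sub.groupby("species")["plot_id"].agg(set).to_dict()


def abundance_change_table(
    table: CensusTable,
    year_start: int,
    year_end: int,
    denominator: str = "union",
) -> pd.DataFrame:
    """Zone-wise counts, contributions, %CC and range index between two years.

    One row per (zone, species) pair present at either census, mirroring the
    layout of a published abundance-change table.  All values are unrounded;
    round at presentation.  Columns: ``species, zone, count_start,
    contrib_start, count_end, contrib_end, cc_percent, range_index``.
    """
    for y in (year_start, year_end):
        if y not in table.years:
            raise ValueError(f"census year {y} not present in table")
    zones = list(dict.fromkeys(table.metadata["zone"]))
    rows = []
    for zone in zones:
        start = _zone_species_counts(table, zone, year_start)
        end = _zone_species_counts(table, zone, year_end)
        cc_recs = {r.species: r for r in percent_composition_change(start, end, zone)}
        rng_recs = {
            r.species: r
            for r in range_change_index(
                _zone_occupancy(table, zone, year_start),
                _zone_occupancy(table, zone, year_end),
                zone,
                denominator,
            )
        }
        for sp in sorted(set(cc_recs) | set(rng_recs)):
            c = cc_recs.get(sp)
            r = rng_recs.get(sp)
            rows.append({
                "species": sp,
                "zone": zone,
                "count_start": c.count_start if c else 0,
                "contrib_start": c.contrib_start if c else 0.0,
                "count_end": c.count_end if c else 0,
                "contrib_end": c.contrib_end if c else 0.0,
                "cc_percent": c.cc if c else np.nan,
                "range_index": r.index if r else np.nan,
            })
    return pd.DataFrame(rows)


def zone_totals(table: CensusTable, years: Sequence[int]) -> pd.DataFrame:
    """Total tree counts per (zone, year), mirroring a Totals row."""
    rec = table.records
    sub = rec.loc[rec["year"].isin(list(years))]
    return (
        sub.groupby(["zone", "year"])["count"].sum().rename("total").reset_index()
    )
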