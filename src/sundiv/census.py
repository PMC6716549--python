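"""Census tables: the long-format data model shared by every analysis.

A census table holds one row per (plot, census year, species) with an integer
tree tally, alongside plot metadata (ecological zone, planar coordinates in
meters, plot area in hectares).  Absences may be recorded explicitly (count 0)
or left implicit; both normalize to the same abundance matrix.

The module also ships, as packaged CSVs, the published zone-level abundance
table for the Sundarbans plot network (three salinity zones, censuses 1986 and
2014, 25 species), exposed through :func:`table1_fixture`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

ZONES = ("hyposaline", "mesosaline", "hypersaline")

CENSUS_COLUMNS = ["plot_id", "zone", "year", "species", "count"]
METADATA_COLUMNS = ["plot_id", "zone", "x", "y", "area_ha"]

DEFAULT_PLOT_AREA_HA = 0.2


class SchemaError(ValueError):
    """A CSV is missing required columns."""


class ValidationError(ValueError):
    """A table violates the census-data invariants."""


class ReferentialError(ValidationError):
    """A census row references a plot absent from the metadata."""


class EmptySelectionError(ValueError):
    """A grouping spec selected no (plot, year) cells."""


@dataclass
class CensusTable:
    """Validated long-format census records plus plot metadata.

    Parameters
    ----------
    records
        DataFrame with columns ``plot_id, zone, year, species, count``.
    metadata
        DataFrame with columns ``plot_id, zone, x, y, area_ha``.  Coordinates
        may be missing (NaN) when the network has no published geometry; any
        spatial operation will then refuse to run rather than invent geometry.
    """

    records: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)
        self.metadata = self.metadata.reset_index(drop=True)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        for col in CENSUS_COLUMNS:
            if col not in self.records.columns:
                raise SchemaError(f"census table is missing column {col!r}")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise SchemaError(f"metadata table is missing column {col!r}")

        rec = self.records
        counts = rec["count"]
        if counts.isna().any() or (np.asarray(counts, dtype=float) % 1 != 0).any():
            row = int(rec.index[counts.isna() | (np.asarray(counts, dtype=float) % 1 != 0)][0])
            raise ValidationError(f"non-integer count at census row {row}")
        if (counts < 0).any():
            row = int(rec.index[counts < 0][0])
            raise ValidationError(f"negative count at census row {row}")
        self.records["count"] = counts.astype(np.int64)
        self.records["year"] = rec["year"].astype(np.int64)
        self.records["species"] = rec["species"].astype(str).str.strip()
        self.records["plot_id"] = rec["plot_id"].astype(str).str.strip()

        bad_zone = set(rec["zone"]) - set(ZONES)
        if bad_zone:
            raise ValidationError(f"unknown zone(s): {sorted(bad_zone)}")
        dup = rec.duplicated(subset=["plot_id", "year", "species"])
        if dup.any():
            key = rec.loc[dup.idxmax(), ["plot_id", "year", "species"]].tolist()
            raise ValidationError(f"duplicate (plot, year, species) record: {key}")
        nz = rec.groupby("plot_id")["zone"].nunique()
        if (nz > 1).any():
            raise ValidationError(
                f"plot {nz.index[nz.gt(1).values][0]!r} changes zone across records"
            )

        meta = self.metadata
        if meta["plot_id"].duplicated().any():
            raise ValidationError("duplicate plot_id in metadata")
        missing = set(rec["plot_id"]) - set(meta["plot_id"])
        if missing:
            raise ReferentialError(
                f"census plots absent from metadata: {sorted(missing)[:5]}"
            )
        for col in ("x", "y"):
            vals = np.asarray(meta[col], dtype=float)
            if np.isinf(vals).any():
                raise ValidationError(f"non-finite {col} coordinate in metadata")
        zmap = dict(zip(meta["plot_id"], meta["zone"]))
        mismatch = rec.loc[rec["zone"] != rec["plot_id"].map(zmap)]
        if len(mismatch):
            raise ValidationError(
                f"zone disagrees with metadata for plot {mismatch['plot_id'].iloc[0]!r}"
            )

    # -- convenience ------------------------------------------------------
    @property
    def years(self) -> list[int]:
        return sorted(self.records["year"].unique().tolist())

    @property
    def species(self) -> list[str]:
        return sorted(self.records.loc[self.records["count"] > 0, "species"].unique())

    @property
    def plots(self) -> list[str]:
        return self.metadata["plot_id"].tolist()

    def has_coordinates(self) -> bool:
        return bool(
            np.isfinite(np.asarray(self.metadata[["x", "y"]], dtype=float)).all()
        )

    def zone_of(self) -> dict[str, str]:
        return dict(zip(self.metadata["plot_id"], self.metadata["zone"]))

    def coordinates(self) -> np.ndarray:
        """(n_plots, 2) array of planar coordinates, metadata order."""
        xy = np.asarray(self.metadata[["x", "y"]], dtype=float)
        if not np.isfinite(xy).all():
            raise ValidationError("table has no complete plot coordinates")
        return xy


def read_census(path, metadata_path) -> CensusTable:
    """Read and validate a census CSV plus its plot-metadata CSV."""
    records = pd.read_csv(path)
    metadata = pd.read_csv(metadata_path)
    missing = [c for c in CENSUS_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"census file {path} is missing column(s) {missing}")
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise SchemaError(f"metadata file {metadata_path} is missing column(s) {missing}")
    try:
        records["count"] = pd.to_numeric(records["count"])
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric count in {path}: {exc}") from None
    return CensusTable(records[CENSUS_COLUMNS], metadata[METADATA_COLUMNS])


def write_census(table: CensusTable, path, metadata_path=None) -> None:
    """Write the table (and optionally its metadata) as schema CSVs.

    Output is byte-stable: fixed column order, record order preserved.
    ``read_census(write_census(t))`` reproduces ``t`` record for record.
    """
    table.records[CENSUS_COLUMNS].to_csv(path, index=False)
    if metadata_path is not None:
        table.metadata[METADATA_COLUMNS].to_csv(metadata_path, index=False)


def table1_fixture() -> CensusTable:
    """The published zone-level abundance table as a pseudo-plot census.

    One "plot" per salinity zone, years 1986 and 2014, all 25 listed species;
    dash cells in the printed table are encoded as explicit zero counts.  The
    zone pseudo-plots carry no coordinates.
    """
    pkg = resources.files("sundiv") / "data"
    with resources.as_file(pkg / "abundance_table_census.csv") as cpath, \
            resources.as_file(pkg / "abundance_table_metadata.csv") as mpath:
        return read_census(cpath, mpath)


GroupingSpec = Mapping[str, tuple[Sequence[str] | None, Sequence[int] | None]]


def to_abundance_matrix(
    table: CensusTable,
    groups: GroupingSpec | Callable[[str, int], str | None],
) -> tuple[np.ndarray, list[str], list[str]]:
    """Aggregate census records into a species x subcommunity count matrix.

    Parameters
    ----------
    groups
        Either an ordered mapping ``label -> (plot_ids | None, years | None)``
        (``None`` selects all), or a callable ``(plot_id, year) -> label``
        returning ``None`` for cells to exclude.  Column order follows mapping
        order, or first appearance in the table for a callable.

    Returns
    -------
    counts, species, labels
        Integer matrix (species rows pruned of all-zero totals), row labels,
        column labels.
    """
    rec = table.records
    if callable(groups):
        labels_series = pd.Series(
            [groups(p, y) for p, y in zip(rec["plot_id"], rec["year"])],
            index=rec.index, dtype=object,
        )
        sel = rec.loc[labels_series.notna()].copy()
        sel["_label"] = labels_series.dropna()
        column_order = list(dict.fromkeys(sel["_label"]))
    else:
        frames = []
        column_order = list(groups)
        for label, (plot_ids, years) in groups.items():
            mask = pd.Series(True, index=rec.index)
            if plot_ids is not None:
                mask &= rec["plot_id"].isin(list(plot_ids))
            if years is not None:
                mask &= rec["year"].isin(list(years))
            sub = rec.loc[mask].copy()
            sub["_label"] = label
            frames.append(sub)
        sel = pd.concat(frames) if frames else rec.iloc[:0].assign(_label=None)
    if not len(sel):
        raise EmptySelectionError("grouping spec selected no census records")

    pivot = sel.pivot_table(
        index="species", columns="_label", values="count", aggfunc="sum", fill_value=0
    )
    pivot = pivot.reindex(columns=[c for c in column_order if c in pivot.columns])
    pivot = pivot.loc[pivot.sum(axis=1) > 0]
    if pivot.empty:
        raise EmptySelectionError("grouping spec selected only zero counts")
    counts = np.asarray(pivot, dtype=np.int64)
    return counts, pivot.index.tolist(), pivot.columns.tolist()
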