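"""Occurrence-record ingestion, filtering and grid aggregation.

Presence records arrive as CSV tables with columns
``species,longitude,latitude,year,range,source`` where ``range`` labels each
record as coming from the species' native or introduced distribution.
Records with incomplete or unparseable coordinates, coordinates outside the
valid lon/lat domain, or observation years before a cutoff (default 1950)
are dropped, and every drop is counted per reason in a filter report.
Surviving records are then aggregated to the analysis grid: one record per
occupied cell, so modelling never sees duplicated presences within a cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import ClimateStack, GridGeometry

__all__ = ["OccurrenceSet", "read_occurrences", "aggregate_to_cells", "extract_env"]

REQUIRED_COLUMNS = ("longitude", "latitude", "year")
RANGE_LABELS = ("native", "introduced")


@dataclass
class OccurrenceSet:
    """Filtered presence records, optionally aggregated to grid cells.

    ``records`` always carries longitude/latitude/year/range/source columns;
    after aggregation it additionally carries ``row``/``col`` cell indices
    (unique per record) and coordinates are cell centres.
    """

    records: pd.DataFrame
    aggregated: bool = False
    filter_report: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def cell_ids(self) -> pd.DataFrame:
        if not self.aggregated:
            raise ValueError("occurrence set is not aggregated")
        return self.records[["row", "col"]]

    def subset(self, range_label: str) -> "OccurrenceSet":
        if range_label not in RANGE_LABELS:
            raise ValueError(f"range label must be one of {RANGE_LABELS}")
        sub = self.records[self.records["range"] == range_label].reset_index(drop=True)
        return OccurrenceSet(sub, aggregated=self.aggregated)


def read_occurrences(table_path: str | Path, min_year: int = 1950) -> OccurrenceSet:
    """Read an occurrence CSV, dropping imprecise or pre-cutoff records.

    Rules (each counted separately in the filter report):

    * missing or unparseable longitude/latitude -> ``incomplete coordinates``
    * coordinates outside [-180, 180] x [-90, 90] -> ``coordinates out of range``
    * missing/unparseable year, or year < ``min_year`` (boundary inclusive:
      ``min_year`` itself is kept) -> ``missing year`` / ``year before cutoff``

    Raises a ``ValueError`` naming the column when a required column is
    absent; individual bad rows are rejected row-wise, never fatally.
    """
    df = pd.read_csv(table_path)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"occurrence table is missing required column {col!r}")
    for optional, default in (("species", "unknown"), ("range", "native"), ("source", "")):
        if optional not in df.columns:
            df[optional] = default

    n_read = len(df)
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    year = pd.to_numeric(df["year"], errors="coerce")

    incomplete = lon.isna() | lat.isna()
    out_of_range = ~incomplete & ((lon.abs() > 180) | (lat.abs() > 90))
    no_year = ~incomplete & ~out_of_range & year.isna()
    too_old = ~incomplete & ~out_of_range & ~no_year & (year < min_year)
    keep = ~(incomplete | out_of_range | no_year | too_old)

    report = {
        "read": int(n_read),
        "dropped": {
            "incomplete coordinates": int(incomplete.sum()),
            "coordinates out of range": int(out_of_range.sum()),
            "missing year": int(no_year.sum()),
            "year before cutoff": int(too_old.sum()),
        },
        "kept": int(keep.sum()),
        "min_year": int(min_year),
    }

    out = df.loc[keep, ["species", "longitude", "latitude", "year", "range", "source"]].copy()
    out["longitude"] = lon[keep]
    out["latitude"] = lat[keep]
    out["year"] = year[keep].astype(int)
    out["range"] = out["range"].astype(str).str.strip().str.lower()
    bad_label = ~out["range"].isin(RANGE_LABELS)
    if bad_label.any():
        warnings.warn(f"{int(bad_label.sum())} records have unknown range labels; kept verbatim")
    return OccurrenceSet(out.reset_index(drop=True), aggregated=False, filter_report=report)


def aggregate_to_cells(occ: OccurrenceSet, geometry: GridGeometry | ClimateStack) -> OccurrenceSet:
    """Collapse records to one per occupied grid cell.

    A cell holding records of both range labels takes the majority label,
    ties resolved to ``native``.  The aggregated record sits at the cell
    centre and keeps the earliest year observed in the cell.  Records outside
    the grid extent are excluded with a warning.  Aggregating an already
    aggregated set is the identity.
    """
    if isinstance(geometry, ClimateStack):
        geometry = geometry.geometry
    if occ.aggregated:
        return occ

    df = occ.records
    cells = [geometry.cell_of(lo, la) for lo, la in zip(df["longitude"], df["latitude"])]
    outside = [c is None for c in cells]
    if any(outside):
        warnings.warn(f"{sum(outside)} occurrence records fall outside the grid extent; excluded")
    df = df.loc[[not o for o in outside]].copy()
    df["row"] = [c[0] for c in cells if c is not None]
    df["col"] = [c[1] for c in cells if c is not None]

    rows = []
    for (i, j), grp in df.groupby(["row", "col"], sort=True):
        counts = grp["range"].value_counts()
        n_native = int(counts.get("native", 0))
        n_intro = int(counts.get("introduced", 0))
        label = "native" if n_native >= n_intro else "introduced"
        lon, lat = geometry.cell_center(i, j)
        rows.append({
            "species": grp["species"].iloc[0],
            "longitude": lon,
            "latitude": lat,
            "year": int(grp["year"].min()),
            "range": label,
            "source": "aggregated",
            "row": int(i),
            "col": int(j),
            "n_records": len(grp),
        })
    agg = pd.DataFrame(rows, columns=["species", "longitude", "latitude", "year",
                                      "range", "source", "row", "col", "n_records"])
    return OccurrenceSet(agg, aggregated=True, filter_report=dict(occ.filter_report))


def extract_env(occ: OccurrenceSet, stack: ClimateStack) -> pd.DataFrame:
    """Environment table for aggregated occurrences (rows = records).

    Returns one column per stack variable plus a boolean ``masked`` column
    flagging records on non-terrestrial cells (their values are NaN).
    """
    if not occ.aggregated:
        raise ValueError("extract_env requires an aggregated occurrence set")
    rows = occ.records["row"].to_numpy()
    cols = occ.records["col"].to_numpy()
    if rows.size and (rows.max() >= stack.geometry.n_rows or cols.max() >= stack.geometry.n_cols):
        raise ValueError("occurrence cells are not on the stack's grid")
    env = stack.env_table(rows, cols)
    env["masked"] = ~stack.mask[rows, cols]
    return env
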