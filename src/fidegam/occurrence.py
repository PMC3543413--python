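"""Data model and I/O for multi-unit occurrence databases.

An occurrence database is a long-format table with one row per
(sampling record, species) incidence.  A *sampling record* is a single
input of occurrence information (a herbarium sheet, a releve, a field
note ...) that contributes one or more species to exactly one sampling
unit (typically a grid cell).  All downstream completeness measures
operate on the per-unit record-by-species incidence matrix built here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ColumnMapping",
    "OccurrenceTable",
    "UnitIncidence",
    "load_occurrences",
    "to_incidence",
    "unit_summaries",
]

#: canonical internal column names
_COLS = ("unit_id", "record_id", "species_id")


@dataclass(frozen=True)
class ColumnMapping:
    """Maps CSV column names onto (unit, record, species)."""

    unit: str = "unit"
    record: str = "record"
    species: str = "species"


class ConfigurationError(ValueError):
    """A required input column is missing or the mapping is invalid."""


@dataclass
class OccurrenceTable:
    """De-duplicated long-format occurrence data.

    ``data`` has exactly the columns ``unit_id``, ``record_id``,
    ``species_id`` (strings), sorted by (unit_id, record_id, species_id),
    one row per incidence.  Every record_id belongs to exactly one unit.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _COLS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"missing columns: {missing}")
        if df.empty:
            raise ValueError("occurrence table is empty")
        df = df.loc[:, list(_COLS)].astype(str)
        if (df["species_id"].str.strip() == "").any():
            raise ValueError("empty species cells are not allowed")
        df = (
            df.drop_duplicates()
            .sort_values(list(_COLS), kind="mergesort")
            .reset_index(drop=True)
        )
        per_record_units = df.groupby("record_id")["unit_id"].nunique()
        bad = per_record_units[per_record_units > 1]
        if len(bad):
            raise ValueError(
                f"record ids mapped to multiple units: {list(bad.index[:5])}"
            )
        self.data = df

    @property
    def unit_ids(self) -> list[str]:
        return sorted(self.data["unit_id"].unique())

    def n_records(self, unit_id: str | None = None) -> int:
        df = self.data
        if unit_id is not None:
            df = df[df["unit_id"] == unit_id]
        return df["record_id"].nunique()

    def subset(self, unit_ids) -> "OccurrenceTable":
        keep = self.data["unit_id"].isin(list(unit_ids))
        return OccurrenceTable(self.data[keep].copy())

    def species_of_unit(self, unit_id: str) -> list[str]:
        df = self.data[self.data["unit_id"] == unit_id]
        if df.empty:
            raise KeyError(f"unknown unit: {unit_id}")
        return sorted(df["species_id"].unique())

    def write_csv(self, path: str | Path, mapping: ColumnMapping = ColumnMapping()) -> None:
        out = self.data.rename(
            columns={
                "unit_id": mapping.unit,
                "record_id": mapping.record,
                "species_id": mapping.species,
            }
        )
        out.to_csv(path, index=False)


@dataclass
class UnitIncidence:
    """Binary record-by-species incidence matrix for one sampling unit.

    Rows are sampling records (H of them), columns are species in order
    of first appearance.  Every row has at least one presence; every
    column has at least one presence, so S_obs equals the column count.
    """

    unit_id: str
    record_ids: list[str]
    species_ids: list[str]
    matrix: np.ndarray  # H x S, uint8

    @property
    def H(self) -> int:
        return self.matrix.shape[0]

    @property
    def S_obs(self) -> int:
        return self.matrix.shape[1]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.uint8)
        if m.ndim != 2 or m.shape != (len(self.record_ids), len(self.species_ids)):
            raise ValueError("matrix shape does not match record/species lists")
        if m.size and (m.sum(axis=1) == 0).any():
            raise ValueError("every record must contain at least one species")
        if m.size and (m.sum(axis=0) == 0).any():
            raise ValueError("every species column must have at least one presence")
        self.matrix = m

    @property
    def species_record_counts(self) -> np.ndarray:
        """Number of records each species occurs in (length S_obs)."""
        return self.matrix.sum(axis=0).astype(int)


def load_occurrences(
    path: str | Path, mapping: ColumnMapping = ColumnMapping()
) -> OccurrenceTable:
    """Read a long-format occurrence CSV into an :class:`OccurrenceTable`.

    The CSV must be UTF-8 with a header row; ``mapping`` names the unit,
    record and species columns (defaults ``unit``/``record``/``species``).
    Extra columns are ignored.  Duplicate (record, species) pairs are
    dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty input file: {path}") from exc
    for attr in ("unit", "record", "species"):
        col = getattr(mapping, attr)
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} (mapped to {attr}) not present in {path.name}; "
                f"found {list(df.columns)}"
            )
    df = df.rename(
        columns={
            mapping.unit: "unit_id",
            mapping.record: "record_id",
            mapping.species: "species_id",
        }
    )
    df = df.dropna(subset=["species_id"])
    return OccurrenceTable(df)


def to_incidence(table: OccurrenceTable, unit_id: str) -> UnitIncidence:
    """Build the incidence matrix of one unit.

    Row order follows sorted record ids; column order is the order in
    which species first appear when records are scanned in that order.
    """
    df = table.data[table.data["unit_id"] == unit_id]
    if df.empty:
        raise KeyError(f"unknown unit: {unit_id}")
    record_ids = sorted(df["record_id"].unique())
    rec_index = {r: i for i, r in enumerate(record_ids)}
    species_ids: list[str] = []
    sp_index: dict[str, int] = {}
    rows, cols = [], []
    for rec, sp in zip(df["record_id"], df["species_id"]):
        if sp not in sp_index:
            sp_index[sp] = len(species_ids)
            species_ids.append(sp)
        rows.append(rec_index[rec])
        cols.append(sp_index[sp])
    # first-appearance order: scan records in row order
    order = np.lexsort((cols, rows))
    species_ids2: list[str] = []
    remap: dict[int, int] = {}
    for k in order:
        c = cols[k]
        if c not in remap:
            remap[c] = len(species_ids2)
            species_ids2.append(species_ids[c])
    m = np.zeros((len(record_ids), len(species_ids2)), dtype=np.uint8)
    for r, c in zip(rows, cols):
        m[r, remap[c]] = 1
    return UnitIncidence(unit_id, record_ids, species_ids2, m)


def unit_summaries(table: OccurrenceTable) -> pd.DataFrame:
    """Per-unit summary (unit_id, H, S_obs)."""
    g = table.data.groupby("unit_id")
    out = pd.DataFrame(
        {
            "unit_id": sorted(g.groups),
            "H": g["record_id"].nunique().reindex(sorted(g.groups)).to_numpy(),
            "S_obs": g["species_id"].nunique().reindex(sorted(g.groups)).to_numpy(),
        }
    )
    return out


def write_unit_summaries_json(table: OccurrenceTable, path: str | Path) -> None:
    recs = unit_summaries(table).to_dict(orient="records")
    Path(path).write_text(json.dumps(recs, indent=1))
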