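"""Virtual-ecologist simulator: a complete-knowledge occurrence database
and its low-exhaustiveness counterpart.

The full database emulates an exhaustively surveyed region: 180 sampling
units, each assigned one of three sampling-intensity levels (20-50,
51-80 or 81-110 records), every record carrying 1-30 species drawn
uniformly without replacement from a 400-species pool.  The full
database is taken to have detected each unit's true richness.

The low-exhaustiveness database re-runs the record-generation procedure
per unit using the information gathered in the full database: the record
count is redrawn uniformly between 3 and min(25, H_full), and each new
record draws its species from the unit's *gathered* species set, with
the per-record species count capped at 20.  Species-level nesting holds
(a unit's subsampled species are a subset of its true species), so
100 * SR_sub / SR_true is a genuine per-unit detection percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .occurrence import OccurrenceTable
from .sac import unit_seed

__all__ = [
    "SimulationConfig",
    "SimulatedDatabase",
    "simulate_simulau",
    "subsample_simulau",
    "true_completeness",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated occurrence database."""

    n_units: int = 180
    intensity_bins: tuple[tuple[int, int], ...] = ((20, 50), (51, 80), (81, 110))
    pool_size: int = 400
    species_per_record: tuple[int, int] = (1, 30)
    sub_max_records: int = 25
    sub_min_records: int = 3
    sub_max_species_per_record: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        bins = sorted(self.intensity_bins)
        if any(lo > hi or lo < 1 for lo, hi in bins):
            raise ValueError("intensity bins must be non-empty ranges")
        if any(a[1] >= b[0] for a, b in zip(bins, bins[1:])):
            raise ValueError("intensity bins must not overlap")
        lo, hi = self.species_per_record
        if not 1 <= lo <= hi <= self.pool_size:
            raise ValueError("species_per_record range invalid for pool size")
        if self.sub_min_records < 1 or self.sub_max_records < self.sub_min_records:
            raise ValueError("invalid subsample record bounds")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


@dataclass
class SimulatedDatabase:
    """Occurrence table plus per-unit true richness and provenance."""

    occurrences: OccurrenceTable
    true_richness: dict[str, int]
    config: SimulationConfig
    stage: str  # "full" | "subsampled"
    _sub_richness: dict[str, int] = field(default_factory=dict)

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for u in sorted(self.true_richness):
            row = {"unit_id": u, "SR_true": self.true_richness[u]}
            if self.stage == "subsampled":
                row["SR_sub"] = self._sub_richness[u]
                row["completeness_pct"] = 100.0 * row["SR_sub"] / row["SR_true"]
            rows.append(row)
        return pd.DataFrame(rows)


def _unit_labels(n_units: int) -> list[str]:
    width = max(3, len(str(n_units)))
    return [f"u{i + 1:0{width}d}" for i in range(n_units)]


def simulate_simulau(config: SimulationConfig = SimulationConfig()) -> SimulatedDatabase:
    """Generate the complete-knowledge database.

    Per unit: pick an intensity bin uniformly at random, draw the record
    count uniformly within it, then fill each record with a uniform
    1-30 draw of distinct species from the common pool.  True richness
    is the unit's observed richness (complete-knowledge assumption).
    """
    species_names = [f"sp{i + 1:03d}" for i in range(config.pool_size)]
    lo_c, hi_c = config.species_per_record
    rows_unit, rows_rec, rows_sp = [], [], []
    true_richness: dict[str, int] = {}
    for u in _unit_labels(config.n_units):
        rng = np.random.default_rng(unit_seed(config.seed, "full:" + u))
        lo, hi = config.intensity_bins[rng.integers(len(config.intensity_bins))]
        H = int(rng.integers(lo, hi + 1))
        seen: set[int] = set()
        for r in range(H):
            c = int(rng.integers(lo_c, hi_c + 1))
            sp = rng.choice(config.pool_size, size=c, replace=False)
            seen.update(int(s) for s in sp)
            rid = f"{u}-r{r + 1:03d}"
            rows_unit.extend([u] * c)
            rows_rec.extend([rid] * c)
            rows_sp.extend(species_names[int(s)] for s in sp)
        true_richness[u] = len(seen)
    table = OccurrenceTable(
        pd.DataFrame(
            {"unit_id": rows_unit, "record_id": rows_rec, "species_id": rows_sp}
        )
    )
    return SimulatedDatabase(table, true_richness, config, "full")


def subsample_simulau(
    sim: SimulatedDatabase, config: SimulationConfig | None = None
) -> SimulatedDatabase:
    """Regenerate each unit at low exhaustiveness from its gathered pool.

    Record counts are uniform on [sub_min_records, min(sub_max_records,
    H_full)]; each record's species count repeats the full-database draw
    (uniform on species_per_record) truncated at the cap and at the
    unit's gathered-pool size; species are drawn uniformly without
    replacement from the unit's gathered species set.
    """
    if sim.stage != "full":
        raise ValueError("subsampling requires a full-stage database")
    config = config or sim.config
    df = sim.occurrences.data
    lo_c, hi_c = config.species_per_record
    cap = config.sub_max_species_per_record
    rows_unit, rows_rec, rows_sp = [], [], []
    sub_richness: dict[str, int] = {}
    for u, g in df.groupby("unit_id", sort=True):
        rng = np.random.default_rng(unit_seed(config.seed, "sub:" + u))
        pool_u = np.sort(g["species_id"].unique())
        H_full = g["record_id"].nunique()
        hi_h = min(config.sub_max_records, H_full)
        if hi_h < config.sub_min_records:
            raise ValueError(
                f"unit {u}: H_full={H_full} below the {config.sub_min_records}-record minimum"
            )
        h = int(rng.integers(config.sub_min_records, hi_h + 1))
        seen: set[str] = set()
        for r in range(h):
            c = min(int(rng.integers(lo_c, hi_c + 1)), cap, len(pool_u))
            sp = rng.choice(pool_u, size=c, replace=False)
            seen.update(sp)
            rid = f"{u}-s{r + 1:03d}"
            rows_unit.extend([u] * c)
            rows_rec.extend([rid] * c)
            rows_sp.extend(sp)
        sub_richness[str(u)] = len(seen)
    table = OccurrenceTable(
        pd.DataFrame(
            {"unit_id": rows_unit, "record_id": rows_rec, "species_id": rows_sp}
        )
    )
    return SimulatedDatabase(
        table, dict(sim.true_richness), config, "subsampled", sub_richness
    )


def true_completeness(sim_sub: SimulatedDatabase) -> pd.Series:
    """Per-unit detection percentage 100 * SR_sub / SR_true."""
    if sim_sub.stage != "subsampled":
        raise ValueError("true completeness requires a subsampled database")
    out = {}
    for u, sr_true in sim_sub.true_richness.items():
        if sr_true == 0:
            raise ValueError(f"unit {u}: SR_true is zero")
        out[u] = 100.0 * sim_sub._sub_richness[u] / sr_true
    return pd.Series(out).sort_index()
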