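import numpy as np
import pandas as pd
import pytest

from fidegam.occurrence import OccurrenceTable, UnitIncidence


def make_incidence(unit_id, records):
    """Build a UnitIncidence from a list of species lists (one per record)."""
    species = []
    for rec in records:
        for sp in rec:
            if sp not in species:
                species.append(sp)
    m = np.zeros((len(records), len(species)), dtype=np.uint8)
    for i, rec in enumerate(records):
        for sp in rec:
            m[i, species.index(sp)] = 1
    rec_ids = [f"r{i + 1}" for i in range(len(records))]
    return UnitIncidence(unit_id, rec_ids, species, m)


def make_table(unit_records):
    """Build an OccurrenceTable from {unit_id: [species lists per record]}."""
    rows = []
    for u, records in unit_records.items():
        for i, rec in enumerate(records):
            for sp in rec:
                rows.append((u, f"{u}-r{i + 1}", sp))
    return OccurrenceTable(
        pd.DataFrame(rows, columns=["unit_id", "record_id", "species_id"])
    )


@pytest.fixture
def toy_incidence():
    """4 records, 3 species: small enough for exhaustive enumeration."""
    return make_incidence("toy", [["A", "B"], ["B"], ["C"], ["A", "C"]])


@pytest.fixture
def two_unit_table():
    return make_table(
        {
            "u1": [["A", "B"], ["B", "C"], ["A"]],
            "u2": [["D"], ["D", "E"], ["E", "F"], ["F"]],
        }
    )
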