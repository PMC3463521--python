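import pandas as pd
import pytest

from quadrivalent.io_cli import (
    fixture_path,
    read_counts,
    read_lengths,
    read_measurements,
)


@pytest.fixture(scope="session")
def survey_counts() -> pd.DataFrame:
    """Packaged population-survey karyomorph counts (33 populations)."""
    return read_counts(fixture_path("table1_counts.csv"))


@pytest.fixture(scope="session")
def length_table() -> pd.DataFrame:
    """Packaged heteromorphic-chromosome lengths for ten measured cells."""
    return read_lengths(fixture_path("table4_lengths.csv"))


@pytest.fixture(scope="session")
def idiogram_cells() -> dict:
    """Measurement records of the two packaged reference idiogram cells."""
    records = read_measurements(fixture_path("table5_measurements.csv"))
    cells: dict[str, list] = {}
    for r in records:
        cells.setdefault(r.cell_id, []).append(r)
    return cells
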