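import pandas as pd
import pytest

import peptaibiomics as pb
from peptaibiomics import io as pio


@pytest.fixture(scope="session")
def lib():
    return pb.default_library()


@pytest.fixture(scope="session")
def sf1_table():
    """Packaged SF1-peptaibol compound table (all rows)."""
    return pio.load_sf1_table()


@pytest.fixture(scope="session")
def sf1_table_curated():
    """Rows whose printed b/y/[M+H]+ reproduce from their sequences."""
    return pio.load_sf1_table(curated_only=True)


@pytest.fixture(scope="session")
def lipo_table():
    return pio.load_lipopeptaibol_table()


@pytest.fixture(scope="session")
def lipo_table_curated():
    return pio.load_lipopeptaibol_table(curated_only=True)


@pytest.fixture(scope="session")
def reference_db():
    return pio.load_reference_fixture()


@pytest.fixture(scope="session")
def by_name(sf1_table):
    """Parse a named compound from the SF1 table."""

    def get(name: str) -> pb.SequenceModel:
        row = sf1_table[sf1_table["name"] == name]
        assert len(row) == 1, f"{name} not unique in fixture"
        rt = row["rt"].iloc[0]
        return pb.parse_sequence(row["sequence"].iloc[0], label=name, rt=float(rt))

    return get
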