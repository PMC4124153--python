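import pytest

from triplify import load_class_graph, load_vocabulary
from triplify.tabular import Column, SourceTable


@pytest.fixture(scope="session")
def vocab():
    return load_vocabulary()


@pytest.fixture(scope="session")
def class_graph():
    return load_class_graph()


@pytest.fixture
def flat_occurrence_table():
    """Four rows sharing one locality, with distinct occurrence IDs."""
    return SourceTable(
        name="occ",
        columns=[
            Column("occurrenceID"), Column("scientificName"),
            Column("locality"), Column("country"), Column("eventDate"),
        ],
        rows=[
            ("OCC1", "Quercus alba", "Sagehen Creek", "United States", "1998-04-12"),
            ("OCC2", "Quercus alba", "Sagehen Creek", "United States", "1998-04-12"),
            ("OCC3", "Danaus plexippus", "Sagehen Creek", "United States", "2003-07-30"),
            ("OCC4", "", "Sagehen Creek", "United States", "2003-07-30"),
        ],
    )


def write_csv(path, text):
    path.write_text(text, encoding="utf-8")
    return path
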