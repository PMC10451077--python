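import pytest

from mosaicmito.fixture import load_table1_fixture
from mosaicmito.reference import load_reference
from mosaicmito.variants import load_marker_table, load_trna_table

from pathlib import Path

DATA = Path(__file__).resolve().parents[1] / "src" / "mosaicmito" / "_data"


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def marker_table():
    return load_marker_table(DATA / "haplogroup_markers_mini.tsv")


@pytest.fixture(scope="session")
def trna_table():
    return load_trna_table(DATA / "trna_pathogenic_mini.tsv")


@pytest.fixture(scope="session")
def fixture_cohort():
    return load_table1_fixture()
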