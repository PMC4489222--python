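import pytest

from msamap.alnio import AlignedSequence, NumberingTable
from msamap.fixtures import make_fixture_bundle, make_structure_variant
from msamap.mapping import LookupAlignment


@pytest.fixture(scope="session")
def plain_bundle(tmp_path_factory):
    """20 sequences x 120 ancestral positions, no engineered features."""
    return make_fixture_bundle(tmp_path_factory.mktemp("plain"), seed=7)


@pytest.fixture(scope="session")
def insert_bundle(tmp_path_factory):
    """Engineered 9-nt insert replacing lookup positions 40-51, plus a
    missing span 60-63 — the crystallization-construct scenario."""
    return make_fixture_bundle(
        tmp_path_factory.mktemp("insert"),
        seed=11,
        insert_span=(40, 51),
        insert_seq="GGGAAACCC",
        missing_span=(60, 63),
    )


@pytest.fixture(scope="session")
def identity_bundle(tmp_path_factory):
    """Gapless, mutation-free alignment: every map is the identity."""
    return make_fixture_bundle(
        tmp_path_factory.mktemp("identity"),
        n=5,
        length=60,
        sub_rate=0.0,
        indel_rate=0.0,
        seed=3,
    )


@pytest.fixture
def toy_lookup_alignment():
    """The engineered-insert schematic: pdb 'ACG--UU' vs lookup 'ACGGA-U'
    (structure residue 4 has no lookup equivalent)."""
    pdb = AlignedSequence("pdb", "ACG--UU")
    lookup = AlignedSequence("ref", "ACGGA-U")
    numbering = NumberingTable.default(5)
    return LookupAlignment(pdb, lookup, numbering, "ref")
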