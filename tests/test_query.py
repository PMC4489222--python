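"""Query validation against the service limits and extraction of column
intervals."""

import pytest

from msamap.alnio import AlignedSequence, NumberingTable
from msamap.errors import (
    EndpointsOutOfOrderError,
    NoDataError,
    RangeTooLongError,
    TooManyRangesError,
    UnknownResidueError,
)
from msamap.mapping import Mapper, build_column_map, build_residue_map
from msamap.query import Limits, extract, resolve_columns, validate_query
from msamap.unitid import parse_unit_id, parse_units_string


def _unit(number, chain="A"):
    return parse_unit_id(f"TEST|1|{chain}||{number}")


def _single(number):
    (r,) = parse_units_string(f"TEST|1|A||{number}")
    return r


def _range(start, end):
    (r,) = parse_units_string(f"TEST|1|A||{start}:TEST|1|A||{end}")
    return r


@pytest.fixture(scope="module")
def identity_maps():
    """100-residue identity chain: polymer index == natural == column."""
    seq = ("ACGU" * 25)
    from msamap.alnio import AlignedSequence
    from msamap.mapping import LookupAlignment

    la = LookupAlignment(
        AlignedSequence("pdb", seq), AlignedSequence("ref", seq),
        NumberingTable.default(100), "ref",
    )
    rm = build_residue_map(la)
    cm = build_column_map([AlignedSequence("ref", seq)], "ref")
    return la.numbering, rm, cm


class TestLimits:
    def test_five_ranges_accepted_six_rejected(self, identity_maps):
        numbering, rm, _ = identity_maps
        five = [_single(i) for i in range(1, 6)]
        assert len(validate_query(five, numbering, rm).ranges) == 5
        six = [_single(i) for i in range(1, 7)]
        with pytest.raises(TooManyRangesError):
            validate_query(six, numbering, rm)

    def test_span_50_accepted_51_rejected(self, identity_maps):
        numbering, rm, _ = identity_maps
        q = validate_query([_range(1, 50)], numbering, rm)
        assert q.ranges[0].span == 50
        with pytest.raises(RangeTooLongError):
            validate_query([_range(1, 51)], numbering, rm)

    def test_endpoints_out_of_order(self, identity_maps):
        numbering, rm, _ = identity_maps
        with pytest.raises(EndpointsOutOfOrderError):
            validate_query([_range(35, 30)], numbering, rm)

    def test_unknown_residue(self, identity_maps):
        numbering, rm, _ = identity_maps
        with pytest.raises(UnknownResidueError):
            validate_query([_single(101)], numbering, rm)

    def test_limits_are_configurable(self, identity_maps):
        numbering, rm, _ = identity_maps
        tight = Limits(max_ranges=1, max_span=3)
        with pytest.raises(RangeTooLongError):
            validate_query([_range(1, 4)], numbering, rm, tight)
        with pytest.raises(TooManyRangesError):
            validate_query([_single(1), _single(2)], numbering, rm, tight)

    def test_ranges_in_any_order_and_overlapping(self, identity_maps):
        numbering, rm, _ = identity_maps
        q = validate_query([_range(60, 70), _range(10, 20), _range(15, 25)], numbering, rm)
        assert [(r.start_polymer_index, r.end_polymer_index) for r in q.ranges] == [
            (60, 70), (10, 20), (15, 25)
        ]


class TestUnmappedEndpoints:
    def test_insert_endpoint_fails_with_no_data_message(self, insert_bundle):
        m = Mapper.build(insert_bundle.lookup_alignment, insert_bundle.msa)
        numbering = insert_bundle.lookup_alignment.numbering
        insert_pi = next(
            i + 1 for i, p in enumerate(insert_bundle.truth.natural) if p is None
        )
        number, ins = numbering.residue_key(insert_pi)
        (r,) = parse_units_string(
            f"{insert_bundle.pdb_id}|1|A||{number}"
            + (f"|||{ins}" if ins else "")
        )
        with pytest.raises(NoDataError) as exc_info:
            validate_query([r], numbering, m.rm)
        assert str(exc_info.value.message) == "No data available in table"

    def test_bridging_the_insert_succeeds(self, insert_bundle):
        """Endpoints flanking an engineered insert are legal; the insert
        residues simply contribute no columns."""
        m = Mapper.build(insert_bundle.lookup_alignment, insert_bundle.msa)
        numbering = insert_bundle.lookup_alignment.numbering
        naturals = insert_bundle.truth.natural
        first_insert = next(i for i, p in enumerate(naturals) if p is None)
        last_insert = max(i for i, p in enumerate(naturals) if p is None)
        start_pi = first_insert      # polymer index of the residue before the insert
        end_pi = last_insert + 2     # polymer index of the residue after the insert
        start_key = numbering.residue_key(start_pi)
        end_key = numbering.residue_key(end_pi)
        units = (
            f"{insert_bundle.pdb_id}|1|A||{start_key[0]}:"
            f"{insert_bundle.pdb_id}|1|A||{end_key[0]}"
        )
        q = validate_query(parse_units_string(units), numbering, m.rm)
        q = resolve_columns(q, m.rm, m.cm, m.offset)
        r = q.ranges[0]
        assert r.start_column == m.cm[naturals[start_pi - 1]]
        assert r.end_column == m.cm[naturals[end_pi - 1]]


class TestResolveAndExtract:
    def test_identity_range_columns(self, identity_maps):
        numbering, rm, cm = identity_maps
        q = validate_query([_range(2, 4)], numbering, rm)
        q = resolve_columns(q, rm, cm)
        assert (q.ranges[0].start_column, q.ranges[0].end_column) == (2, 4)

    def test_interval_includes_lookup_gap_columns(self):
        msa = [AlignedSequence("ref", "AC-GGAU"), AlignedSequence("s", "ACUGGAU")]
        from msamap.mapping import LookupAlignment

        la = LookupAlignment(
            AlignedSequence("pdb", "ACGGAU"), AlignedSequence("ref", "ACGGAU"),
            NumberingTable.default(6), "ref",
        )
        m = Mapper.build(la, msa)
        q = validate_query([_range(2, 3)], la.numbering, m.rm)
        q = resolve_columns(q, m.rm, m.cm, m.offset)
        r = q.ranges[0]
        assert (r.start_column, r.end_column, r.width) == (2, 4, 3)

    def test_extract_toy_msa(self, identity_maps):
        numbering, rm, cm = identity_maps
        msa = [
            AlignedSequence("a", "ACGU" * 25),
            AlignedSequence("b", ("AC-U" * 25)),
            AlignedSequence("c", ("A-GU" * 25)),
        ]
        q = resolve_columns(validate_query([_range(2, 3)], numbering, rm), rm, cm)
        es = extract(q, msa)
        assert es.extracts["a"] == ["CG"]
        assert es.extracts["b"] == ["C-"]
        assert es.extracts["c"] == ["-G"]

    def test_display_joins_ranges_with_comma(self, identity_maps):
        numbering, rm, cm = identity_maps
        msa = [AlignedSequence("a", "ACGU" + "A" * 96)]
        q = resolve_columns(
            validate_query([_single(1), _single(4)], numbering, rm), rm, cm
        )
        es = extract(q, msa)
        assert es.display("a") == "A, U"

    def test_extract_width_invariance(self, insert_bundle):
        m = Mapper.build(insert_bundle.lookup_alignment, insert_bundle.msa)
        numbering = insert_bundle.lookup_alignment.numbering
        q = resolve_columns(
            validate_query([_bundle_range(insert_bundle, 5, 30)], numbering, m.rm),
            m.rm, m.cm, m.offset,
        )
        es = extract(q, insert_bundle.msa)
        widths = {len(es.extracts[sid][0]) for sid in es.seq_ids}
        assert widths == {q.ranges[0].width}

    def test_concatenation_property(self, insert_bundle):
        """Extracting column intervals [a,b] and [b+1,c] and concatenating
        equals extracting [a,c], for every sequence."""
        from dataclasses import replace

        from msamap.query import RangeQuery

        m = Mapper.build(insert_bundle.lookup_alignment, insert_bundle.msa)
        numbering = insert_bundle.lookup_alignment.numbering
        whole = resolve_columns(
            validate_query([_bundle_range(insert_bundle, 5, 30)], numbering, m.rm),
            m.rm, m.cm, m.offset,
        )
        (w,) = whole.ranges
        for b in (w.start_column, w.start_column + 7, w.end_column - 1):
            parts = RangeQuery(
                [replace(w, end_column=b), replace(w, start_column=b + 1)],
                whole.limits,
            )
            es_whole = extract(whole, insert_bundle.msa)
            es_parts = extract(parts, insert_bundle.msa)
            for sid in es_whole.seq_ids:
                assert "".join(es_parts.extracts[sid]) == es_whole.extracts[sid][0]


def _bundle_range(bundle, start_number, end_number):
    from msamap.unitid import parse_units_string as p

    (r,) = p(f"{bundle.pdb_id}|1|A||{start_number}:{bundle.pdb_id}|1|A||{end_number}")
    return r
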