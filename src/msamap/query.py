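"""Range-query validation and execution.

A query is a list of inclusive residue ranges on one structure chain. The
validator enforces the service limits — at most 5 ranges, at most 50
structure residues per range — and requires both endpoints of every range
to have lookup-sequence equivalents; an endpoint on an engineered insert
fails with the error text "No data available in table". Ranges may be
listed in any order, but within each range the endpoints must be in
increasing polymer order (numbering-table order, so insertion-code runs
like 190, 190A .. 190L validate correctly).

Execution resolves each range to an inclusive column interval of the Data
Alignment — including interior columns where the lookup row is gapped,
i.e. insertions present only in other sequences — and slices every
sequence's row over those intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .alnio import AlignedSequence, NumberingTable
from .errors import (
    EndpointsOutOfOrderError,
    NoDataError,
    RangeTooLongError,
    TooManyRangesError,
    UnknownResidueError,
)
from .mapping import UNMAPPED, ColumnMap, ResidueMap
from .unitid import UnitRange, format_unit_id

__all__ = [
    "Limits",
    "DEFAULT_LIMITS",
    "ResolvedRange",
    "RangeQuery",
    "ExtractSet",
    "RANGE_SEPARATOR",
    "validate_query",
    "resolve_columns",
    "extract",
]

RANGE_SEPARATOR = ", "


@dataclass(frozen=True)
class Limits:
    """Query limits; defaults are the service's published values."""

    max_ranges: int = 5
    max_span: int = 50


DEFAULT_LIMITS = Limits()


@dataclass(frozen=True)
class ResolvedRange:
    """One query range after endpoint resolution."""

    unit_range: UnitRange
    start_polymer_index: int
    end_polymer_index: int
    start_column: Optional[int] = None
    end_column: Optional[int] = None

    @property
    def span(self) -> int:
        """Inclusive structure-residue count."""
        return self.end_polymer_index - self.start_polymer_index + 1

    @property
    def width(self) -> int:
        """Inclusive column count; requires resolved columns."""
        assert self.start_column is not None and self.end_column is not None
        return self.end_column - self.start_column + 1


@dataclass(frozen=True)
class RangeQuery:
    """A validated query: ordered ranges with resolved endpoints."""

    ranges: list[ResolvedRange]
    limits: Limits = DEFAULT_LIMITS


@dataclass(frozen=True)
class ExtractSet:
    """Per-sequence column extracts, one gapped string per range, in query
    order, plus the comma-joined display string."""

    seq_ids: list[str]
    extracts: dict[str, list[str]]

    def display(self, seq_id: str) -> str:
        return RANGE_SEPARATOR.join(self.extracts[seq_id])


def _resolve_endpoint(
    unit, numbering: NumberingTable, rm: ResidueMap, which: str
) -> int:
    number, ins = unit.residue_key()
    pi = numbering.polymer_index(number, ins)
    if pi is None:
        raise UnknownResidueError(
            f"{which} endpoint {format_unit_id(unit)}: residue {number}{ins} "
            "not present in the chain"
        )
    if rm[pi] is UNMAPPED:
        # endpoint has no equivalent position in the lookup sequence
        raise NoDataError()
    return pi


def validate_query(
    ranges: list[UnitRange],
    numbering: NumberingTable,
    rm: ResidueMap,
    limits: Limits = DEFAULT_LIMITS,
) -> RangeQuery:
    """Check limits and resolve every endpoint to a polymer index.

    The per-range span counts structure residues (polymer indices), not
    alignment columns. Overlapping or duplicate ranges are allowed.
    """
    if not ranges:
        raise UnknownResidueError("query contains no ranges")
    if len(ranges) > limits.max_ranges:
        raise TooManyRangesError(
            f"{len(ranges)} ranges requested; at most {limits.max_ranges} allowed"
        )
    resolved = []
    for r in ranges:
        start_pi = _resolve_endpoint(r.start, numbering, rm, "start")
        end_pi = _resolve_endpoint(r.end, numbering, rm, "end")
        if start_pi > end_pi:
            raise EndpointsOutOfOrderError(
                f"range {format_unit_id(r.start)}:{format_unit_id(r.end)} endpoints "
                "are not in increasing order"
            )
        span = end_pi - start_pi + 1
        if span > limits.max_span:
            raise RangeTooLongError(
                f"range spans {span} residues; at most {limits.max_span} allowed"
            )
        resolved.append(ResolvedRange(r, start_pi, end_pi))
    return RangeQuery(resolved, limits)


def resolve_columns(
    q: RangeQuery, rm: ResidueMap, cm: ColumnMap, offset: int = 0
) -> RangeQuery:
    """Map each range's endpoints through the residue and column maps to an
    inclusive column interval of the Data Alignment."""
    resolved = []
    for r in q.ranges:
        start_nat = rm[r.start_polymer_index]
        end_nat = rm[r.end_polymer_index]
        assert start_nat is not UNMAPPED and end_nat is not UNMAPPED
        resolved.append(
            replace(r, start_column=cm[start_nat + offset], end_column=cm[end_nat + offset])
        )
    return RangeQuery(resolved, q.limits)


def extract(q: RangeQuery, msa: list[AlignedSequence]) -> ExtractSet:
    """Slice every sequence's row over each resolved column interval.

    Sequences whose extracts are all gaps are retained: a deletion is data.
    """
    extracts: dict[str, list[str]] = {}
    for s in msa:
        extracts[s.seq_id] = [
            s.row[r.start_column - 1 : r.end_column] for r in q.ranges
        ]
    return ExtractSet([s.seq_id for s in msa], extracts)
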