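"""Sequence Summary and Sequence Details reporting.

The Sequence Summary groups the extracted column blocks into distinct
variants with occurrence counts and percentages of the total number of
sequences. The Sequence Details table has one row per alignment sequence:
its identifier, the extract, GenBank accession, NCBI taxonomy ID, organism
name and taxonomic lineage, plus two highlight flags — ``matches_structure``
(the extract equals the 3D structure's own sequence over the query; shown
green in the original interface) and ``is_lookup`` (the reference sequence
used for the mapping; shown blue).

Serialization: JSON (query echo + both tables, unpaginated), TSV (details
table), and gapped FASTA/Clustal sub-alignments of the extracted columns
with per-range blocks concatenated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .alnio import (
    GAP,
    AlignedSequence,
    SequenceMetadata,
    format_alignment,
    normalize_residues,
)
from .errors import UsageError
from .mapping import UNMAPPED, LookupAlignment, ResidueMap
from .query import RANGE_SEPARATOR, ExtractSet, RangeQuery
from .unitid import format_units_string

__all__ = [
    "SummaryRow",
    "DetailRow",
    "QueryResult",
    "summarize",
    "structure_extract",
    "flag_rows",
    "filter_rows",
    "serialize",
    "SERIALIZATION_FORMATS",
]

SERIALIZATION_FORMATS = ("json", "tsv", "fasta", "clustal")
SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class SummaryRow:
    """One distinct sequence variant with its frequency."""

    variant: str
    count: int
    percent: float
    matches_structure: bool = False

    @property
    def percent_str(self) -> str:
        return f"{self.percent:.2f}"

    def search_text(self) -> str:
        return self.variant


@dataclass(frozen=True)
class DetailRow:
    """One alignment sequence with its extract and provenance."""

    seq_id: str
    crw_id: str
    variant: str
    accession: str
    taxonomy_id: str
    organism: str
    lineage: str
    matches_structure: bool = False
    is_lookup: bool = False

    def search_text(self) -> str:
        return "\t".join(
            (self.crw_id, self.variant, self.accession, self.taxonomy_id,
             self.organism, self.lineage)
        )


@dataclass(frozen=True)
class QueryResult:
    """Executed query, ready for serialization."""

    units: str
    alignment_id: str
    query: RangeQuery
    extracts: ExtractSet
    summary: list[SummaryRow]
    details: list[DetailRow]


def summarize(es: ExtractSet) -> list[SummaryRow]:
    """Group sequences by display string; order by count descending, then
    variant ascending (a deterministic tie-break). Percentages are computed
    at full precision on the total number of sequences."""
    counts: dict[str, int] = {}
    for seq_id in es.seq_ids:
        display = es.display(seq_id)
        counts[display] = counts.get(display, 0) + 1
    total = len(es.seq_ids)
    rows = [
        SummaryRow(variant, count, 100.0 * count / total)
        for variant, count in counts.items()
    ]
    rows.sort(key=lambda r: (-r.count, r.variant))
    return rows


def structure_extract(la: LookupAlignment, rm: ResidueMap, q: RangeQuery) -> list[str]:
    """Per range, the gap-free 3D-structure letters over the *mapped*
    residues of the range. Insert residues have no alignment columns, so
    they cannot participate in the comparison."""
    letters = la.pdb_row.ungapped()
    out = []
    for r in q.ranges:
        out.append(
            "".join(
                letters[pi - 1]
                for pi in range(r.start_polymer_index, r.end_polymer_index + 1)
                if rm[pi] is not UNMAPPED
            )
        )
    return out


def _variant_matches_structure(extracts: list[str], structure: list[str]) -> bool:
    return len(extracts) == len(structure) and all(
        normalize_residues(e.replace(GAP, "")) == normalize_residues(s)
        for e, s in zip(extracts, structure)
    )


def flag_rows(
    es: ExtractSet,
    summary: list[SummaryRow],
    structure: list[str],
    lookup_id: str,
    metadata: Optional[Sequence[SequenceMetadata]] = None,
) -> tuple[list[SummaryRow], list[DetailRow]]:
    """Attach highlight flags and metadata.

    Returns the summary with ``matches_structure`` set per variant and a
    details table with exactly one row per alignment sequence in alignment
    order. Sequences without metadata get empty metadata fields.
    """
    meta_by_id = {m.seq_id: m for m in (metadata or [])}
    details = []
    for seq_id in es.seq_ids:
        m = meta_by_id.get(seq_id, SequenceMetadata(seq_id=seq_id))
        details.append(
            DetailRow(
                seq_id=seq_id,
                crw_id=m.crw_id or seq_id,
                variant=es.display(seq_id),
                accession=m.accession,
                taxonomy_id=m.taxonomy_id,
                organism=m.organism,
                lineage=m.lineage,
                matches_structure=_variant_matches_structure(es.extracts[seq_id], structure),
                is_lookup=(seq_id == lookup_id),
            )
        )
    structure_display = RANGE_SEPARATOR.join(structure)
    flagged_summary = []
    for row in summary:
        stripped = RANGE_SEPARATOR.join(
            part.replace(GAP, "") for part in row.variant.split(RANGE_SEPARATOR)
        )
        matches = normalize_residues(stripped) == normalize_residues(structure_display)
        flagged_summary.append(
            SummaryRow(row.variant, row.count, row.percent, matches_structure=matches)
        )
    return flagged_summary, details


def filter_rows(
    rows: Sequence[Union[SummaryRow, DetailRow]], pattern: str
) -> list[Union[SummaryRow, DetailRow]]:
    """Display-level filter: retain rows whose searchable text contains the
    pattern as a literal, case-insensitive substring. Gaps count as
    characters, so filtering for "ACGU" excludes "AC-GU". Counts in the
    summary are never recomputed by filtering."""
    if not pattern:
        raise UsageError("filter pattern must be non-empty")
    needle = pattern.lower()
    return [r for r in rows if needle in r.search_text().lower()]


def _sub_alignment(result: QueryResult) -> list[AlignedSequence]:
    # FASTA/Clustal cannot carry the comma separator, so range blocks are
    # simply concatenated.
    return [
        AlignedSequence(seq_id, "".join(result.extracts.extracts[seq_id]))
        for seq_id in result.extracts.seq_ids
    ]


def _to_json(result: QueryResult) -> str:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "query": {
            "units": result.units,
            "alignment_id": result.alignment_id,
            "limits": {
                "max_ranges": result.query.limits.max_ranges,
                "max_span": result.query.limits.max_span,
            },
            "ranges": [
                {
                    "units": format_units_string([r.unit_range]),
                    "start_polymer_index": r.start_polymer_index,
                    "end_polymer_index": r.end_polymer_index,
                    "start_column": r.start_column,
                    "end_column": r.end_column,
                }
                for r in result.query.ranges
            ],
        },
        "summary": [
            {
                "variant": s.variant,
                "count": s.count,
                "percent": s.percent_str,
                "matches_structure": s.matches_structure,
            }
            for s in result.summary
        ],
        "details": [
            {
                "seq_id": d.seq_id,
                "crw_id": d.crw_id,
                "variant": d.variant,
                "accession": d.accession,
                "taxonomy_id": d.taxonomy_id,
                "organism": d.organism,
                "lineage": d.lineage,
                "matches_structure": d.matches_structure,
                "is_lookup": d.is_lookup,
            }
            for d in result.details
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=False) + "\n"


_TSV_HEADER = [
    "crw_id", "variant", "accession", "taxonomy_id", "organism", "lineage",
    "matches_structure", "is_lookup",
]


def _to_tsv(result: QueryResult) -> str:
    lines = ["\t".join(_TSV_HEADER)]
    for d in result.details:
        lines.append(
            "\t".join(
                (d.crw_id, d.variant, d.accession, d.taxonomy_id, d.organism,
                 d.lineage, str(d.matches_structure).lower(), str(d.is_lookup).lower())
            )
        )
    return "\n".join(lines) + "\n"


def serialize(result: QueryResult, format: str) -> str:
    """Render a query result as json, tsv, fasta or clustal."""
    if format == "json":
        return _to_json(result)
    if format == "tsv":
        return _to_tsv(result)
    if format in ("fasta", "clustal"):
        return format_alignment(_sub_alignment(result), format)
    raise UsageError(f"unknown output format {format!r}; use one of {SERIALIZATION_FORMATS}")
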