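"""Gapped-alignment, residue-numbering and metadata I/O.

Formats supported: gapped FASTA and Clustal for alignments (via biopython),
tab-separated tables with a header for the numbering sidecar and the
per-sequence metadata. Gap characters ``.`` and ``~`` are normalized to
``-`` on input and residue letters are uppercased; ``T`` is preserved as
written (DNA-alphabet GenBank entries), with T treated as equivalent to U
wherever sequences are compared.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DuplicateIdError,
    DuplicateResidueKeyError,
    EmptyInputError,
    FormatError,
    UsageError,
)

__all__ = [
    "AlignedSequence",
    "SequenceMetadata",
    "NumberingTable",
    "GAP",
    "normalize_row",
    "normalize_residues",
    "read_alignment",
    "write_alignment",
    "format_alignment",
    "read_metadata",
    "write_metadata",
    "read_numbering",
    "write_numbering",
]

GAP = "-"
_GAP_CHARS = "-.~"
_GAP_TRANSLATION = str.maketrans({".": GAP, "~": GAP})

METADATA_COLUMNS = ["seq_id", "crw_id", "accession", "taxonomy_id", "organism", "lineage"]
NUMBERING_COLUMNS = ["polymer_index", "residue_number", "insertion_code", "identity"]


@dataclass(frozen=True)
class AlignedSequence:
    """One row of a gapped alignment."""

    seq_id: str
    row: str

    def ungapped(self) -> str:
        return self.row.replace(GAP, "")


@dataclass(frozen=True)
class SequenceMetadata:
    """Identifiers and taxonomy for one alignment sequence; absent values
    are empty strings, never dropped rows."""

    seq_id: str
    crw_id: str = ""
    accession: str = ""
    taxonomy_id: str = ""
    organism: str = ""
    lineage: str = ""


def normalize_row(row: str) -> str:
    """Uppercase and canonicalize gap characters; idempotent."""
    return row.upper().translate(_GAP_TRANSLATION)


def normalize_residues(seq: str) -> str:
    """Comparison form of an ungapped sequence: uppercase, T folded to U."""
    return seq.upper().replace("T", "U")


class NumberingTable:
    """Author residue numbering for one structure chain.

    Maps ``(residue_number, insertion_code)`` keys to 1-based polymer
    indices. Polymer indices are exactly ``1..N`` in file order; keys are
    unique; insertion codes compare case-insensitively.
    """

    def __init__(self, rows: Iterable[tuple[int, int, str, str]]):
        self.rows: list[tuple[int, int, str, str]] = []
        self._index: dict[tuple[int, str], int] = {}
        for i, (polymer_index, number, ins, identity) in enumerate(rows, start=1):
            ins = (ins or "").strip().upper()
            if polymer_index != i:
                raise FormatError(
                    f"numbering table: polymer_index {polymer_index} at row {i}; "
                    "indices must be exactly 1..N in order"
                )
            key = (int(number), ins)
            if key in self._index:
                raise DuplicateResidueKeyError(
                    f"numbering table: duplicate residue key {number}{ins}"
                )
            self.rows.append((i, int(number), ins, identity))
            self._index[key] = i

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, key: tuple[int, str]) -> bool:
        number, ins = key
        return (int(number), (ins or "").upper()) in self._index

    def polymer_index(self, number: int, insertion_code: str = "") -> Optional[int]:
        """1-based polymer index for a residue key, or None if unknown."""
        return self._index.get((int(number), (insertion_code or "").upper()))

    def residue_key(self, polymer_index: int) -> tuple[int, str]:
        _, number, ins, _ = self.rows[polymer_index - 1]
        return (number, ins)

    def identity(self, polymer_index: int) -> str:
        return self.rows[polymer_index - 1][3]

    def label(self, polymer_index: int) -> str:
        number, ins = self.residue_key(polymer_index)
        return f"{number}{ins}"

    @classmethod
    def default(cls, n: int) -> "NumberingTable":
        """Sequential numbering 1..n with no insertion codes, used when no
        sidecar file accompanies a structure sequence."""
        return cls((i, i, "", "") for i in range(1, n + 1))


def _check_format(format: str) -> str:
    if format not in ("fasta", "clustal"):
        raise UsageError(f"unknown alignment format {format!r}; use 'fasta' or 'clustal'")
    return format


def read_alignment(path: Union[str, Path], format: str = "fasta") -> list[AlignedSequence]:
    """Read a gapped alignment, preserving sequence order.

    All rows must share one length; duplicate sequence IDs are rejected.
    The Clustal conservation line, if present, is ignored.
    """
    _check_format(format)
    path = Path(path)
    try:
        if format == "fasta":
            records = list(SeqIO.parse(str(path), "fasta"))
        else:
            records = list(AlignIO.read(str(path), "clustal"))
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as {format}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no sequences found")
    seqs = [AlignedSequence(rec.id, normalize_row(str(rec.seq))) for rec in records]
    width = len(seqs[0].row)
    for s in seqs:
        if len(s.row) != width:
            raise FormatError(
                f"{path}: row {s.seq_id!r} has length {len(s.row)}, expected {width}"
            )
    seen: set[str] = set()
    for s in seqs:
        if s.seq_id in seen:
            raise DuplicateIdError(f"{path}: duplicate sequence id {s.seq_id!r}")
        seen.add(s.seq_id)
    return seqs


def write_alignment(
    seqs: list[AlignedSequence], path: Union[str, Path], format: str = "fasta"
) -> None:
    """Write a gapped alignment; gaps are always written as ``-``."""
    _check_format(format)
    if not seqs:
        raise EmptyInputError("cannot write an empty alignment")
    width = len(seqs[0].row)
    for s in seqs:
        if len(s.row) != width:
            raise FormatError(f"row {s.seq_id!r} has length {len(s.row)}, expected {width}")
    records = [
        SeqRecord(Seq(normalize_row(s.row)), id=s.seq_id, description="") for s in seqs
    ]
    path = Path(path)
    if format == "fasta":
        SeqIO.write(records, str(path), "fasta")
    else:
        AlignIO.write(MultipleSeqAlignment(records), str(path), "clustal")


def format_alignment(seqs: list[AlignedSequence], format: str = "fasta") -> str:
    """Render an alignment to a string in the given format."""
    _check_format(format)
    if not seqs:
        raise EmptyInputError("cannot format an empty alignment")
    records = [
        SeqRecord(Seq(normalize_row(s.row)), id=s.seq_id, description="") for s in seqs
    ]
    buf = io.StringIO()
    if format == "fasta":
        SeqIO.write(records, buf, "fasta")
    else:
        AlignIO.write(MultipleSeqAlignment(records), buf, "clustal")
    return buf.getvalue()


def read_metadata(path: Union[str, Path]) -> list[SequenceMetadata]:
    """Read the per-sequence metadata TSV.

    The header must include ``seq_id``; the other five columns are optional
    and default to empty strings. Unknown extra columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "seq_id" not in df.columns:
        raise FormatError(f"{path}: metadata table lacks a 'seq_id' column")
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    return [
        SequenceMetadata(**{col: str(row[col]) for col in METADATA_COLUMNS})
        for _, row in df.iterrows()
    ]


def write_metadata(records: list[SequenceMetadata], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [{col: getattr(r, col) for col in METADATA_COLUMNS} for r in records],
        columns=METADATA_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_numbering(
    path: Optional[Union[str, Path]], n: Optional[int] = None
) -> NumberingTable:
    """Read the residue-numbering sidecar TSV; if ``path`` is None or the
    file does not exist, synthesize sequential numbering ``1..n``."""
    if path is None or not Path(path).exists():
        if n is None:
            raise UsageError("no numbering file and no sequence length given")
        return NumberingTable.default(n)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in NUMBERING_COLUMNS if c not in df.columns and c != "identity"]
    if missing:
        raise FormatError(f"{path}: numbering table lacks columns {missing}")
    if "identity" not in df.columns:
        df["identity"] = ""
    rows = [
        (int(r["polymer_index"]), int(r["residue_number"]), r["insertion_code"], r["identity"])
        for _, r in df.iterrows()
    ]
    return NumberingTable(rows)


def write_numbering(table: NumberingTable, path: Union[str, Path]) -> None:
    df = pd.DataFrame(table.rows, columns=NUMBERING_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
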