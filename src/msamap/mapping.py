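"""The two-step coordinate map from structure residues to MSA columns.

Step 1 (Lookup Alignment): a pairwise alignment of the structure-derived
sequence against its closest reference ("lookup") sequence assigns each
structure residue a *natural position* — its 1-based index in the ungapped
lookup sequence — or marks it UNMAPPED when it is aligned to a lookup gap
(engineered inserts, unalignable residues).

Step 2 (Data Alignment): the lookup sequence is also a row of the curated
MSA; its k-th non-gap character locates natural position k in an alignment
column. Composing the two maps takes an author residue number (with
optional insertion code) through the numbering table to a polymer index,
then to a natural position, then to an MSA column.

The copy of the lookup sequence in the Data Alignment may carry extra
sequence at either end (a longer GenBank entry); consistency checking
locates the Lookup Alignment's span inside it and returns the natural-
position offset, which the composition adds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .alnio import GAP, AlignedSequence, NumberingTable, normalize_residues
from .errors import (
    InvalidAlignmentError,
    LookupMismatchError,
    LookupNotFoundError,
    UnknownResidueError,
)

__all__ = [
    "UNMAPPED",
    "LookupAlignment",
    "ResidueMap",
    "ColumnMap",
    "build_residue_map",
    "build_column_map",
    "check_consistency",
    "residue_to_column",
    "Mapper",
]


class _Unmapped:
    """Singleton marker for structure residues without a lookup-sequence
    equivalent."""

    _instance: Optional["_Unmapped"] = None

    def __new__(cls) -> "_Unmapped":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNMAPPED"

    def __bool__(self) -> bool:
        return False


UNMAPPED = _Unmapped()

Position = Union[int, _Unmapped]


@dataclass(frozen=True)
class LookupAlignment:
    """Pairwise gapped alignment of structure sequence vs. reference, plus
    the structure chain's residue numbering."""

    pdb_row: AlignedSequence
    lookup_row: AlignedSequence
    numbering: NumberingTable
    lookup_id: str

    def __post_init__(self) -> None:
        if len(self.pdb_row.row) != len(self.lookup_row.row):
            raise InvalidAlignmentError(
                "lookup alignment rows differ in length: "
                f"{len(self.pdb_row.row)} vs {len(self.lookup_row.row)}"
            )
        n = len(self.pdb_row.ungapped())
        if n != len(self.numbering):
            raise InvalidAlignmentError(
                f"structure sequence has {n} residues but numbering table has "
                f"{len(self.numbering)} rows"
            )
        for col, (a, b) in enumerate(zip(self.pdb_row.row, self.lookup_row.row), start=1):
            if a == GAP and b == GAP:
                raise InvalidAlignmentError(f"column {col} is all-gap")


class ResidueMap:
    """Polymer index (1..N) → natural position of the lookup sequence, or
    UNMAPPED. Defined positions are strictly increasing."""

    def __init__(self, positions: list[Position]):
        self._positions = positions

    def __len__(self) -> int:
        return len(self._positions)

    def __getitem__(self, polymer_index: int) -> Position:
        if not 1 <= polymer_index <= len(self._positions):
            raise UnknownResidueError(f"polymer index {polymer_index} out of range 1..{len(self._positions)}")
        return self._positions[polymer_index - 1]

    def is_mapped(self, polymer_index: int) -> bool:
        return self[polymer_index] is not UNMAPPED

    def mapped_items(self) -> list[tuple[int, int]]:
        return [
            (i, p) for i, p in enumerate(self._positions, start=1) if p is not UNMAPPED
        ]


class ColumnMap:
    """Natural position (1..L) → 1-based column of the Data Alignment;
    strictly increasing by construction."""

    def __init__(self, columns: list[int]):
        self._columns = columns

    def __len__(self) -> int:
        return len(self._columns)

    def __getitem__(self, natural_position: int) -> int:
        if not 1 <= natural_position <= len(self._columns):
            raise UnknownResidueError(
                f"natural position {natural_position} out of range 1..{len(self._columns)}"
            )
        return self._columns[natural_position - 1]


def build_residue_map(la: LookupAlignment) -> ResidueMap:
    """Column-by-column scan of the Lookup Alignment: each structure
    residue aligned to a lookup character gets that character's natural
    position; residues aligned to lookup gaps are UNMAPPED."""
    positions: list[Position] = []
    natural = 0
    for a, b in zip(la.pdb_row.row, la.lookup_row.row):
        if b != GAP:
            natural += 1
        if a != GAP:
            positions.append(natural if b != GAP else UNMAPPED)
    return ResidueMap(positions)


def build_column_map(msa: list[AlignedSequence], lookup_id: str) -> ColumnMap:
    """Locate each non-gap character of the lookup row in its MSA column."""
    row = _find_row(msa, lookup_id).row
    return ColumnMap([col for col, ch in enumerate(row, start=1) if ch != GAP])


def _find_row(msa: list[AlignedSequence], seq_id: str) -> AlignedSequence:
    for s in msa:
        if s.seq_id == seq_id:
            return s
    raise LookupNotFoundError(f"lookup sequence {seq_id!r} not present in the data alignment")


def check_consistency(la: LookupAlignment, msa: list[AlignedSequence]) -> int:
    """Verify the two copies of the lookup sequence agree and return the
    natural-position offset of the Lookup Alignment's span within the Data
    Alignment's copy.

    Comparison is case-insensitive with T equivalent to U and is restricted
    to the span covered by the Lookup Alignment, so a Data copy with extra
    5' or 3' sequence passes (offset non-zero for extra 5'). The span must
    occur exactly once; zero matches is a mismatch, several are ambiguous.
    """
    span = normalize_residues(la.lookup_row.ungapped())
    data_seq = normalize_residues(_find_row(msa, la.lookup_id).ungapped())
    if not span:
        raise InvalidAlignmentError("lookup row of the lookup alignment is all-gap")
    first = data_seq.find(span)
    if first < 0:
        # report the first differing natural position for the aligned-at-start case
        limit = min(len(span), len(data_seq))
        diff = next(
            (i + 1 for i in range(limit) if span[i] != data_seq[i]), limit + 1
        )
        raise LookupMismatchError(
            f"lookup sequence {la.lookup_id!r} differs between alignments; "
            f"first differing natural position: {diff}"
        )
    if data_seq.find(span, first + 1) >= 0:
        raise LookupMismatchError(
            f"lookup span occurs more than once in the data copy of {la.lookup_id!r}; "
            "cannot anchor the mapping unambiguously"
        )
    return first


def residue_to_column(
    key: tuple[int, str],
    numbering: NumberingTable,
    rm: ResidueMap,
    cm: ColumnMap,
    offset: int = 0,
) -> Position:
    """Compose the maps for one residue key ``(number, insertion_code)``.

    Returns the 1-based Data Alignment column, or UNMAPPED if the residue
    has no lookup equivalent. ``offset`` shifts natural positions when the
    Data copy of the lookup sequence has extra 5' sequence.
    """
    number, ins = key
    pi = numbering.polymer_index(number, ins)
    if pi is None:
        raise UnknownResidueError(f"residue {number}{(ins or '').upper()} not found in chain numbering")
    natural = rm[pi]
    if natural is UNMAPPED:
        return UNMAPPED
    return cm[natural + offset]


@dataclass(frozen=True)
class Mapper:
    """The assembled translation machinery for one structure chain against
    one data alignment."""

    lookup: LookupAlignment
    msa: list[AlignedSequence]
    rm: ResidueMap
    cm: ColumnMap
    offset: int

    @classmethod
    def build(cls, la: LookupAlignment, msa: list[AlignedSequence]) -> "Mapper":
        offset = check_consistency(la, msa)
        return cls(la, msa, build_residue_map(la), build_column_map(msa, la.lookup_id), offset)

    def column_of(self, key: tuple[int, str]) -> Position:
        return residue_to_column(key, self.lookup.numbering, self.rm, self.cm, self.offset)
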