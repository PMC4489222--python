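"""Unit IDs: pipe-delimited addresses of residues in macromolecular 3D
structure files, and the ``units=`` range-query string built from them.

A Unit ID has up to nine positional fields::

    pdb|model|chain|identity|number|atom|alt_id|insertion_code|symmetry_op

e.g. ``2AW7|1|A||1430`` addresses nucleotide 1430 of chain A, model 1 of
PDB entry 2AW7, and ``1FJG|1|A|U|190|||L`` addresses nucleotide 190L (a
uridine with insertion code L). Trailing empty fields may be omitted in the
serialized form. The residue *identity* field (and atom/alt_id) is carried
but ignored when comparing addresses, since the residue number, insertion
code and chain already identify the position uniquely.

Ranges are written ``start:end`` (inclusive, both endpoints on the same
pdb/model/chain); a lone Unit ID is a single-residue range; commas separate
distinct ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import ParseError

__all__ = [
    "UnitID",
    "UnitRange",
    "parse_unit_id",
    "format_unit_id",
    "query_equal",
    "parse_units_string",
    "format_units_string",
]

_FIELD_NAMES = (
    "pdb_id", "model", "chain", "identity", "number",
    "atom", "alt_id", "insertion_code", "symmetry_op",
)


@dataclass(frozen=True)
class UnitID:
    """Structured residue address within a 3D structure file."""

    pdb_id: str
    model: int
    chain: str
    number: int
    identity: str = ""
    atom: str = ""
    alt_id: str = ""
    insertion_code: str = ""
    symmetry_op: str = ""

    def residue_key(self) -> tuple[int, str]:
        """(number, normalized insertion code) — the key used to look the
        residue up in a chain's numbering table."""
        return (self.number, self.insertion_code.upper())

    def chain_key(self) -> tuple[str, int, str]:
        return (self.pdb_id, self.model, self.chain)


@dataclass(frozen=True)
class UnitRange:
    """Inclusive residue range; ``end`` may equal ``start``."""

    start: UnitID
    end: UnitID

    def __post_init__(self) -> None:
        if self.start.chain_key() != self.end.chain_key():
            raise ParseError(
                "range endpoints must share pdb_id, model and chain: "
                f"{format_unit_id(self.start)} vs {format_unit_id(self.end)}"
            )


def parse_unit_id(text: str) -> UnitID:
    """Parse a pipe-delimited Unit ID string.

    Whitespace around delimiters is stripped (URL copy/paste tolerance).
    At least the first five fields (pdb, model, chain, identity, number)
    must be present; later fields default to empty.
    """
    if not text or not text.strip():
        raise ParseError("empty unit ID")
    fields = [f.strip() for f in text.split("|")]
    if len(fields) < 5:
        raise ParseError(
            f"unit ID {text!r} has {len(fields)} fields; at least 5 required "
            "(pdb|model|chain|identity|number)"
        )
    if len(fields) > 9:
        raise ParseError(f"unit ID {text!r} has more than 9 fields")
    fields += [""] * (9 - len(fields))
    pdb_id, model_s, chain, identity, number_s = fields[:5]
    atom, alt_id, insertion_code, symmetry_op = fields[5:]
    if not pdb_id:
        raise ParseError(f"unit ID {text!r}: empty pdb_id field")
    if not chain:
        raise ParseError(f"unit ID {text!r}: empty chain field")
    try:
        model = int(model_s)
    except ValueError:
        raise ParseError(f"unit ID {text!r}: model {model_s!r} is not an integer") from None
    if model <= 0:
        raise ParseError(f"unit ID {text!r}: model must be positive, got {model}")
    try:
        number = int(number_s)
    except ValueError:
        raise ParseError(f"unit ID {text!r}: residue number {number_s!r} is not an integer") from None
    return UnitID(
        pdb_id=pdb_id, model=model, chain=chain, identity=identity,
        number=number, atom=atom, alt_id=alt_id,
        insertion_code=insertion_code, symmetry_op=symmetry_op,
    )


def format_unit_id(u: UnitID) -> str:
    """Serialize to the canonical pipe-delimited form, trimming trailing
    empty fields (internal empties are kept as empty strings)."""
    fields = [
        u.pdb_id, str(u.model), u.chain, u.identity, str(u.number),
        u.atom, u.alt_id, u.insertion_code, u.symmetry_op,
    ]
    while len(fields) > 5 and fields[-1] == "":
        fields.pop()
    return "|".join(fields)


def query_equal(a: UnitID, b: UnitID) -> bool:
    """Address equality as used for queries: identity, atom and alt_id are
    ignored; insertion codes compare case-insensitively; symmetry operators
    compare only when both are present."""
    if (a.pdb_id, a.model, a.chain, a.number) != (b.pdb_id, b.model, b.chain, b.number):
        return False
    if a.insertion_code.upper() != b.insertion_code.upper():
        return False
    if a.symmetry_op and b.symmetry_op and a.symmetry_op != b.symmetry_op:
        return False
    return True


def parse_units_string(text: str) -> list[UnitRange]:
    """Parse a ``units=`` query fragment into an ordered list of ranges.

    Each comma-separated item is either ``A:B`` (inclusive range) or a
    single Unit ID (start == end). Endpoint order within a range is *not*
    checked here — that requires the chain's numbering table and is done by
    query validation.
    """
    if not text or not text.strip():
        raise ParseError("empty units string")
    ranges: list[UnitRange] = []
    for item in text.split(","):
        item = item.strip()
        if not item:
            raise ParseError("empty range item in units string")
        parts = item.split(":")
        if len(parts) == 1:
            u = parse_unit_id(parts[0])
            ranges.append(UnitRange(u, u))
        elif len(parts) == 2:
            if not parts[0].strip() or not parts[1].strip():
                raise ParseError(f"range item {item!r} has a dangling colon")
            start = parse_unit_id(parts[0])
            end = parse_unit_id(parts[1])
            ranges.append(UnitRange(start, end))
        else:
            raise ParseError(f"range item {item!r} has more than one colon")
    return ranges


def format_units_string(ranges: list[UnitRange]) -> str:
    """Inverse of :func:`parse_units_string` (single-residue ranges are
    written without a colon)."""
    items = []
    for r in ranges:
        if query_equal(r.start, r.end):
            items.append(format_unit_id(r.start))
        else:
            items.append(f"{format_unit_id(r.start)}:{format_unit_id(r.end)}")
    return ",".join(items)
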