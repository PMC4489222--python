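"""Registry of available structure→chain→alignment mappings.

A registry is a declarative YAML file enumerating, per structure chain,
which data alignment(s) it can be queried against and where the supporting
files live (data alignment, lookup alignment, numbering sidecar, metadata
table; paths are relative to the config file). A chain may appear with
several alignments — large-subunit structures typically carry both LSU and
5S rRNA alignments — in which case the caller must select one explicitly;
where only one alignment is available it is selected automatically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import yaml

from .alnio import (
    AlignedSequence,
    NumberingTable,
    SequenceMetadata,
    read_alignment,
    read_metadata,
    read_numbering,
)
from .errors import (
    AmbiguousAlignmentError,
    ConfigError,
    InvalidAlignmentError,
    UnknownStructureError,
)
from .mapping import LookupAlignment, Mapper
from .query import DEFAULT_LIMITS, Limits, extract, resolve_columns, validate_query
from .report import QueryResult, flag_rows, structure_extract, summarize
from .unitid import UnitRange, format_units_string, parse_units_string

__all__ = ["RegistryEntry", "Registry", "load_registry", "select_alignment", "run_query"]

_REQUIRED_KEYS = (
    "pdb_id", "model", "chain", "alignment_id",
    "data_alignment", "lookup_alignment", "lookup_id",
)


@dataclass(frozen=True)
class RegistryEntry:
    """One queryable (structure chain, alignment) pairing."""

    pdb_id: str
    model: int
    chain: str
    molecule: str
    alignment_id: str
    data_alignment: Path
    data_format: str
    lookup_alignment: Path
    lookup_format: str
    lookup_id: str
    numbering: Optional[Path] = None
    metadata: Optional[Path] = None

    def load(self) -> "LoadedEntry":
        """Read all files and assemble the mapper."""
        msa = read_alignment(self.data_alignment, self.data_format)
        pair = read_alignment(self.lookup_alignment, self.lookup_format)
        if len(pair) != 2:
            raise InvalidAlignmentError(
                f"{self.lookup_alignment}: lookup alignment must have exactly 2 rows, "
                f"found {len(pair)}"
            )
        lookup_rows = [s for s in pair if s.seq_id == self.lookup_id]
        if len(lookup_rows) != 1:
            raise InvalidAlignmentError(
                f"{self.lookup_alignment}: expected one row with id {self.lookup_id!r}"
            )
        pdb_row = next(s for s in pair if s.seq_id != self.lookup_id)
        numbering = read_numbering(self.numbering, n=len(pdb_row.ungapped()))
        la = LookupAlignment(pdb_row, lookup_rows[0], numbering, self.lookup_id)
        metadata = read_metadata(self.metadata) if self.metadata else []
        return LoadedEntry(self, la, msa, metadata, Mapper.build(la, msa))


@dataclass(frozen=True)
class LoadedEntry:
    entry: RegistryEntry
    lookup_alignment: LookupAlignment
    msa: list[AlignedSequence]
    metadata: list[SequenceMetadata]
    mapper: Mapper


class Registry:
    def __init__(self, entries: list[RegistryEntry]):
        self.entries = entries
        seen = set()
        for e in entries:
            key = (e.pdb_id, e.model, e.chain, e.alignment_id)
            if key in seen:
                raise ConfigError(
                    f"duplicate registry entry for {e.pdb_id}|{e.model}|{e.chain} "
                    f"with alignment {e.alignment_id!r}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def load_registry(config: Union[str, Path]) -> Registry:
    """Parse and validate a registry config; every referenced file must
    exist (reported with its path otherwise)."""
    config = Path(config)
    try:
        doc = yaml.safe_load(config.read_text())
    except FileNotFoundError:
        raise ConfigError(f"registry config not found: {config}") from None
    except yaml.YAMLError as exc:
        raise ConfigError(f"{config}: not valid YAML: {exc}") from exc
    if not isinstance(doc, dict) or not isinstance(doc.get("entries"), list):
        raise ConfigError(f"{config}: expected a mapping with an 'entries' list")
    base = config.parent
    entries = []
    for i, raw in enumerate(doc["entries"]):
        missing = [k for k in _REQUIRED_KEYS if k not in raw]
        if missing:
            raise ConfigError(f"{config}: entry {i}: missing keys {missing}")

        def _path(key: str, required: bool) -> Optional[Path]:
            if key not in raw or raw[key] is None:
                return None
            p = base / str(raw[key])
            if not p.exists():
                if required or key in raw:
                    raise ConfigError(f"{config}: entry {i}: file not found: {p}")
            return p

        entries.append(
            RegistryEntry(
                pdb_id=str(raw["pdb_id"]),
                model=int(raw["model"]),
                chain=str(raw["chain"]),
                molecule=str(raw.get("molecule", "")),
                alignment_id=str(raw["alignment_id"]),
                data_alignment=_path("data_alignment", required=True),
                data_format=str(raw.get("data_format", "fasta")),
                lookup_alignment=_path("lookup_alignment", required=True),
                lookup_format=str(raw.get("lookup_format", "fasta")),
                lookup_id=str(raw["lookup_id"]),
                numbering=_path("numbering", required=False),
                metadata=_path("metadata", required=False),
            )
        )
    return Registry(entries)


def select_alignment(
    registry: Registry,
    pdb_id: str,
    chain: Optional[str] = None,
    alignment_id: Optional[str] = None,
    model: Optional[int] = None,
) -> RegistryEntry:
    """Resolve a structure (and optionally chain/model) to a unique
    registry entry; auto-select when only one alignment is available."""
    candidates = [e for e in registry if e.pdb_id == pdb_id]
    if not candidates:
        raise UnknownStructureError(f"structure {pdb_id!r} not in registry")
    if chain is not None:
        candidates = [e for e in candidates if e.chain == chain]
        if not candidates:
            raise UnknownStructureError(f"chain {chain!r} of {pdb_id!r} not in registry")
    if model is not None:
        candidates = [e for e in candidates if e.model == model]
        if not candidates:
            raise UnknownStructureError(f"model {model} of {pdb_id!r} not in registry")
    if alignment_id is not None:
        candidates = [e for e in candidates if e.alignment_id == alignment_id]
        if not candidates:
            raise UnknownStructureError(
                f"alignment {alignment_id!r} not available for {pdb_id!r}"
            )
    if len(candidates) > 1:
        choices = sorted({e.alignment_id for e in candidates})
        raise AmbiguousAlignmentError(
            f"{pdb_id!r} is covered by several alignments; choose one of: "
            + ", ".join(choices)
        )
    return candidates[0]


def run_query(
    loaded: LoadedEntry,
    units: Union[str, list[UnitRange]],
    limits: Limits = DEFAULT_LIMITS,
) -> QueryResult:
    """Execute a units-string (or pre-parsed range list) query end to end:
    validate, resolve columns, extract, summarize, flag."""
    ranges = parse_units_string(units) if isinstance(units, str) else units
    mapper = loaded.mapper
    la = loaded.lookup_alignment
    q = validate_query(ranges, la.numbering, mapper.rm, limits)
    q = resolve_columns(q, mapper.rm, mapper.cm, mapper.offset)
    es = extract(q, loaded.msa)
    summary = summarize(es)
    structure = structure_extract(la, mapper.rm, q)
    summary, details = flag_rows(es, summary, structure, la.lookup_id, loaded.metadata)
    return QueryResult(
        units=format_units_string(ranges),
        alignment_id=loaded.entry.alignment_id,
        query=q,
        extracts=es,
        summary=summary,
        details=details,
    )
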