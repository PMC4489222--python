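"""Synthetic Lookup/Data alignment pairs with exact ground-truth homology.

Real curated rRNA alignments live on remote servers; every mapping and
reporting path here is instead exercised on generated data whose true
residue→column homology is known by construction, not inferred.

The data-alignment simulator mutates an ancestral sequence independently
per sequence, with indels applied at the alignment level: a deletion blanks
a core column in one sequence, an insertion adds brand-new columns private
to one sequence. The first sequence (the "lookup") is the unmutated
ancestor, mirroring a GenBank reference that exactly matches the structure
species. Because columns are bookkept explicitly, the map from each natural
position of the lookup to its alignment column is exact.

The structure-variant builder derives a 3D-structure chain from the lookup
sequence the way crystallized constructs differ from database entries: a
span of the biological sequence may be replaced by an engineered insert
(e.g. a crystallization hairpin) and another span may be missing
(disordered/truncated). Insert residues are UNMAPPED in the truth table;
the chain numbering can optionally carry an insertion-code run (190A-style)
over a chosen span.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .alnio import (
    GAP,
    AlignedSequence,
    NumberingTable,
    SequenceMetadata,
    write_alignment,
    write_metadata,
    write_numbering,
)
from .errors import UsageError
from .mapping import LookupAlignment

__all__ = [
    "RNA_ALPHABET",
    "DNA_ALPHABET",
    "FixtureTruth",
    "simulate_data_alignment",
    "make_structure_variant",
    "make_metadata",
    "FixtureBundle",
    "make_fixture_bundle",
]

RNA_ALPHABET = "ACGU"
DNA_ALPHABET = "ACGT"

DEFAULT_LOOKUP_ID = "lookup"


@dataclass(frozen=True)
class FixtureTruth:
    """Ground truth for one generated fixture.

    ``natural[i]`` is the true natural position (1-based) of structure
    residue with polymer index ``i+1``, or None for unmappable residues;
    ``residue_keys[i]`` its (number, insertion_code) key;
    ``lookup_columns[p-1]`` the true Data Alignment column of natural
    position ``p``.
    """

    natural: list[Optional[int]]
    residue_keys: list[tuple[int, str]]
    lookup_columns: list[int]
    params: dict = field(default_factory=dict)

    def true_column(self, polymer_index: int) -> Optional[int]:
        p = self.natural[polymer_index - 1]
        return None if p is None else self.lookup_columns[p - 1]


def simulate_data_alignment(
    n: int,
    length: int,
    sub_rate: float,
    indel_rate: float,
    seed: int,
    alphabet: str = RNA_ALPHABET,
    lookup_id: str = DEFAULT_LOOKUP_ID,
) -> tuple[list[AlignedSequence], list[int]]:
    """Simulate an MSA of ``n`` sequences descended from one ancestor.

    Returns the alignment (lookup sequence first) and the exact column
    homology of the lookup: a list mapping each natural position 1..length
    to its 1-based alignment column. Deterministic under ``seed``.

    Per non-lookup sequence, each ancestral position is deleted with
    probability ``indel_rate/2`` or substituted with probability
    ``sub_rate``; after each position (and before the first) a private
    insertion of 1-3 residues occurs with probability ``indel_rate/2``.
    """
    if n < 2:
        raise UsageError("need at least 2 sequences (lookup + 1)")
    if length < 1:
        raise UsageError("length must be positive")
    if not (0 <= sub_rate < 1 and 0 <= indel_rate < 1):
        raise UsageError("rates must be in [0, 1)")
    rng = random.Random(seed)
    ancestor = "".join(rng.choice(alphabet) for _ in range(length))

    # columns[c] = list of per-sequence characters; build as column events
    n_others = n - 1
    core_chars: list[list[str]] = []  # per core position, chars for other seqs
    inserts: list[list[tuple[int, str]]] = [[] for _ in range(length + 1)]
    # inserts[slot] holds (seq_index, inserted_string); slot s = after core pos s
    for i in range(n_others):
        if rng.random() < indel_rate / 2:
            inserts[0].append((i, "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 3)))))
    for j in range(length):
        chars = []
        for i in range(n_others):
            if rng.random() < indel_rate / 2:
                chars.append(GAP)
            elif rng.random() < sub_rate:
                chars.append(rng.choice([c for c in alphabet if c != ancestor[j]]))
            else:
                chars.append(ancestor[j])
        core_chars.append(chars)
        for i in range(n_others):
            if rng.random() < indel_rate / 2:
                inserts[j + 1].append(
                    (i, "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 3))))
                )

    rows: list[list[str]] = [[] for _ in range(n)]  # row 0 = lookup
    lookup_columns: list[int] = []
    col = 0

    def emit_inserts(slot: int) -> None:
        nonlocal col
        for seq_index, inserted in sorted(inserts[slot]):
            for ch in inserted:
                col += 1
                for r in range(n):
                    rows[r].append(ch if r == seq_index + 1 else GAP)

    emit_inserts(0)
    for j in range(length):
        col += 1
        lookup_columns.append(col)
        rows[0].append(ancestor[j])
        for i in range(n_others):
            rows[i + 1].append(core_chars[j][i])
        emit_inserts(j + 1)

    width = max(3, len(str(n - 1)))
    seqs = [AlignedSequence(lookup_id, "".join(rows[0]))]
    for i in range(n_others):
        seqs.append(AlignedSequence(f"seq{i + 1:0{width}d}", "".join(rows[i + 1])))
    return seqs, lookup_columns


def make_structure_variant(
    lookup_seq: str,
    insert_span: Optional[tuple[int, int]] = None,
    insert_seq: str = "",
    missing_span: Optional[tuple[int, int]] = None,
    seed: int = 0,
    insertion_code_span: Optional[tuple[int, int]] = None,
    pdb_chain_id: str = "structure",
    lookup_id: str = DEFAULT_LOOKUP_ID,
    rna_structure: bool = False,
) -> tuple[LookupAlignment, NumberingTable, list[Optional[int]]]:
    """Derive a structure chain from a lookup sequence and build its
    pairwise Lookup Alignment plus numbering table and truth map.

    ``insert_span`` (1-based, inclusive, in lookup coordinates) is replaced
    in the structure by ``insert_seq`` (engineered residues, UNMAPPED in the
    truth); ``missing_span`` is simply absent from the structure. Spans must
    be disjoint. ``insertion_code_span`` is a polymer-index span (in the
    *structure* chain) that gets insertion-code numbering: every residue in
    it keeps the previous residue's number with letter codes A, B, C, ...
    ``rna_structure`` transcribes the structure letters to the RNA alphabet
    (T→U), to exercise mixed-alphabet comparison.
    """
    L = len(lookup_seq)
    for name, span in (("insert_span", insert_span), ("missing_span", missing_span)):
        if span is not None:
            a, b = span
            if not (1 <= a <= b <= L):
                raise UsageError(f"{name} {span} outside 1..{L}")
    if insert_span and missing_span:
        a, b = insert_span
        c, d = missing_span
        if not (b < c or d < a):
            raise UsageError(f"insert_span {insert_span} overlaps missing_span {missing_span}")
    if insert_seq and insert_span is None:
        raise UsageError("insert_seq given without insert_span")

    in_insert = (lambda p: insert_span is not None and insert_span[0] <= p <= insert_span[1])
    in_missing = (lambda p: missing_span is not None and missing_span[0] <= p <= missing_span[1])

    pdb_chars: list[str] = []
    lookup_chars: list[str] = []
    natural: list[Optional[int]] = []  # per structure residue

    def structure_letter(ch: str) -> str:
        return ch.upper().replace("T", "U") if rna_structure else ch.upper()

    for p in range(1, L + 1):
        if insert_span is not None and p == insert_span[0]:
            # engineered insert: structure letters against lookup gaps
            for ch in insert_seq:
                pdb_chars.append(structure_letter(ch))
                lookup_chars.append(GAP)
                natural.append(None)
        if in_insert(p) or in_missing(p):
            # biological sequence absent from the structure
            pdb_chars.append(GAP)
            lookup_chars.append(lookup_seq[p - 1])
        else:
            pdb_chars.append(structure_letter(lookup_seq[p - 1]))
            lookup_chars.append(lookup_seq[p - 1])
            natural.append(p)

    numbering = _build_numbering(pdb_chars, natural, insertion_code_span)
    la = LookupAlignment(
        pdb_row=AlignedSequence(pdb_chain_id, "".join(pdb_chars)),
        lookup_row=AlignedSequence(lookup_id, "".join(lookup_chars)),
        numbering=numbering,
        lookup_id=lookup_id,
    )
    return la, numbering, natural


def _build_numbering(
    pdb_chars: list[str],
    natural: list[Optional[int]],
    insertion_code_span: Optional[tuple[int, int]],
) -> NumberingTable:
    letters = [ch for ch in pdb_chars if ch != GAP]
    rows = []
    number = 0
    code_pos = 0
    for pi, letter in enumerate(letters, start=1):
        if insertion_code_span and insertion_code_span[0] <= pi <= insertion_code_span[1]:
            base = max(number, 1)
            code = string.ascii_uppercase[code_pos]
            code_pos += 1
            rows.append((pi, base, code, letter))
        else:
            number += 1
            code_pos = 0
            rows.append((pi, number, "", letter))
    return NumberingTable(rows)


_GENERA = [
    ("Escherichia", "coli", "Bacteria; Proteobacteria; Gammaproteobacteria; Enterobacterales"),
    ("Salmonella", "enterica", "Bacteria; Proteobacteria; Gammaproteobacteria; Enterobacterales"),
    ("Vibrio", "cholerae", "Bacteria; Proteobacteria; Gammaproteobacteria; Vibrionales"),
    ("Bacillus", "subtilis", "Bacteria; Firmicutes; Bacilli; Bacillales"),
    ("Staphylococcus", "aureus", "Bacteria; Firmicutes; Bacilli; Bacillales"),
    ("Thermus", "thermophilus", "Bacteria; Deinococcus-Thermus; Deinococci; Thermales"),
    ("Deinococcus", "radiodurans", "Bacteria; Deinococcus-Thermus; Deinococci; Deinococcales"),
    ("Synechocystis", "sp.", "Bacteria; Cyanobacteria; Synechococcales"),
    ("Mycobacterium", "tuberculosis", "Bacteria; Actinobacteria; Corynebacteriales"),
    ("Helicobacter", "pylori", "Bacteria; Proteobacteria; Epsilonproteobacteria; Campylobacterales"),
]


def make_metadata(seq_ids: list[str], seed: int) -> list[SequenceMetadata]:
    """Deterministic synthetic metadata: CRW-style IDs, accessions,
    taxonomy IDs, organism names and lineages drawn from a small bacterial
    panel (so lineage filtering has something to bite on)."""
    rng = random.Random(seed)
    records = []
    for k, seq_id in enumerate(seq_ids, start=1):
        genus, species, lineage = _GENERA[rng.randrange(len(_GENERA))]
        accession = "".join(rng.choice(string.ascii_uppercase) for _ in range(2)) + \
            f"{rng.randrange(100000, 999999)}"
        records.append(
            SequenceMetadata(
                seq_id=seq_id,
                crw_id=f"crw.{k:05d}",
                accession=accession,
                taxonomy_id=str(rng.randrange(100, 99999)),
                organism=f"{genus} {species}",
                lineage=f"{lineage}; {genus}",
            )
        )
    return records


@dataclass(frozen=True)
class FixtureBundle:
    """A complete on-disk fixture: registry config plus all data files."""

    root: Path
    config_path: Path
    pdb_id: str
    model: int
    chain: str
    alignment_id: str
    lookup_alignment: LookupAlignment
    msa: list[AlignedSequence]
    metadata: list[SequenceMetadata]
    truth: FixtureTruth

    def unit(self, number: int, insertion_code: str = "") -> str:
        ins = f"|||{insertion_code}" if insertion_code else ""
        return f"{self.pdb_id}|{self.model}|{self.chain}||{number}{ins}"


def make_fixture_bundle(
    root: Union[str, Path],
    n: int = 20,
    length: int = 120,
    sub_rate: float = 0.05,
    indel_rate: float = 0.02,
    seed: int = 7,
    insert_span: Optional[tuple[int, int]] = None,
    insert_seq: str = "",
    missing_span: Optional[tuple[int, int]] = None,
    insertion_code_span: Optional[tuple[int, int]] = None,
    pdb_id: str = "2AW7",
    model: int = 1,
    chain: str = "A",
    alignment_id: str = "ssu-mini",
    molecule: str = "SSU rRNA",
    alphabet: str = RNA_ALPHABET,
    format: str = "fasta",
) -> FixtureBundle:
    """Generate a full fixture on disk: data alignment, lookup alignment,
    numbering sidecar, metadata table and a one-entry registry config.

    Deterministic under ``seed``; identical parameters produce identical
    files.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    msa, lookup_columns = simulate_data_alignment(
        n, length, sub_rate, indel_rate, seed, alphabet=alphabet
    )
    lookup_seq = msa[0].ungapped()
    la, numbering, natural = make_structure_variant(
        lookup_seq,
        insert_span=insert_span,
        insert_seq=insert_seq,
        missing_span=missing_span,
        seed=seed + 1,
        insertion_code_span=insertion_code_span,
        pdb_chain_id=f"{pdb_id}|{model}|{chain}",
        rna_structure=(alphabet == DNA_ALPHABET),
    )
    metadata = make_metadata([s.seq_id for s in msa], seed + 2)

    ext = "fasta" if format == "fasta" else "aln"
    data_path = root / f"data.{ext}"
    lookup_path = root / f"lookup.{ext}"
    numbering_path = root / "numbering.tsv"
    metadata_path = root / "metadata.tsv"
    config_path = root / "registry.yaml"

    write_alignment(msa, data_path, format)
    write_alignment([la.pdb_row, la.lookup_row], lookup_path, format)
    write_numbering(numbering, numbering_path)
    write_metadata(metadata, metadata_path)
    config = {
        "entries": [
            {
                "pdb_id": pdb_id,
                "model": model,
                "chain": chain,
                "molecule": molecule,
                "alignment_id": alignment_id,
                "data_alignment": data_path.name,
                "data_format": format,
                "lookup_alignment": lookup_path.name,
                "lookup_format": format,
                "numbering": numbering_path.name,
                "metadata": metadata_path.name,
                "lookup_id": la.lookup_id,
            }
        ]
    }
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))

    truth = FixtureTruth(
        natural=natural,
        residue_keys=[numbering.residue_key(i) for i in range(1, len(numbering) + 1)],
        lookup_columns=lookup_columns,
        params={
            "n": n, "length": length, "sub_rate": sub_rate,
            "indel_rate": indel_rate, "seed": seed,
            "insert_span": insert_span, "insert_seq": insert_seq,
            "missing_span": missing_span,
        },
    )
    return FixtureBundle(
        root=root,
        config_path=config_path,
        pdb_id=pdb_id,
        model=model,
        chain=chain,
        alignment_id=alignment_id,
        lookup_alignment=la,
        msa=msa,
        metadata=metadata,
        truth=truth,
    )
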