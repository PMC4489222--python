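# Methods

## Coordinate model

All coordinates are 1-based and intervals are inclusive, matching the
biologist convention of "natural" numbering: consecutive positive integers
over an ungapped sequence.

Three tables drive the translation from a structure residue to an MSA
column:

- **Numbering table** — for each chain, polymer index 1..N in order, with
  the author residue number, optional insertion code and residue identity.
  Polymer indices must be exactly 1..N; `(number, insertion_code)` keys must
  be unique, with insertion codes compared case-insensitively (conventions
  drift between files). When no sidecar accompanies a chain, sequential
  numbering 1..N is synthesized.
- **Residue map** m₁: polymer index → natural position of the lookup
  sequence, or UNMAPPED. Built by a single column scan of the pairwise
  lookup alignment: a running counter advances on every non-gap lookup
  character; structure residues aligned to lookup characters get the counter
  value, those aligned to lookup gaps are UNMAPPED. A column gapped in both
  rows is rejected as an invalid alignment. No computational distinction is
  made between engineered inserts and ordinary unalignable residues — both
  are simply UNMAPPED.
- **Column map** m₂: natural position → MSA column, read off the lookup
  sequence's gapped row in the data alignment.

Both maps are strictly increasing on their defined domain, so range
endpoints map to a well-ordered column interval. Extraction is purely
column-interval based: the interval `[m₂(m₁(start)), m₂(m₁(end))]` includes
interior columns where the lookup row is gapped (insertions private to other
sequences), and UNMAPPED residues interior to a range simply contribute no
columns — which is what produces the "bridge the insert" behaviour when a
query spans an engineered insert via mapped flanking endpoints.

### Consistency between the two alignments

The lookup sequence appears in both the pairwise lookup alignment and the
data alignment, but database entries are sometimes longer at the 5' or 3'
end than the span the structure was aligned to. Consistency checking
therefore compares the two copies only over the lookup alignment's span:
the span (case-folded, T≡U) must occur exactly once as a substring of the
data copy. Zero occurrences is a mismatch (reported with the first
differing natural position when the sequences disagree in place); multiple
occurrences are rejected as ambiguous anchoring. The match offset shifts
all natural positions before applying m₂.

## Query validation

Limits are configuration with defaults of 5 ranges per query and 50
structure residues per range; the span counts polymer indices, not columns,
because queries are phrased in nucleotide positions of the structure.
Endpoint order is judged in polymer order — numbering-table order — not
numeric residue order, so an insertion-code run `190, 190A, …, 190L`
validates as increasing. Endpoints must be mapped; an UNMAPPED endpoint
raises the no-data error with message text "No data available in table",
and the package always errors rather than clamping to the nearest mapped
neighbour. Overlapping or duplicate ranges are permitted and returned
independently. Ranges may not mix chains, models or structures; one
alignment is selected per query.

## Unit IDs

Fields are positional: `pdb|model|chain|identity|number|atom|alt_id|
insertion_code|symmetry_op`. The first five must be present when parsing;
trailing empty fields are trimmed when formatting; internal empty fields
are preserved. Query-equality ignores identity, atom and alt_id (the
address is already unique without them), compares pdb and chain
case-sensitively (PDB chains are case-sensitive) and insertion codes
case-insensitively, and compares symmetry operators only when both sides
carry one — this keeps equality a congruence for round-tripping while not
penalizing addresses that omit the operator. Whitespace around delimiters
is stripped for copy/paste tolerance. A lone colon at the start or end of a
range item is an error: only closed inclusive ranges exist. Model numbers
are always required.

## Reporting

The summary groups sequences by their display string (per-range extracts
joined with `", "`), counting occurrences and computing percentages at full
precision over the total number of sequences, rendered to two decimals.
Default order is count descending with a lexicographic tie-break on the
variant — any deterministic order would do, but determinism is required for
reproducible output. The `matches_structure` flag compares the gap-stripped
variant per range against the structure's own letters restricted to mapped
residues of that range (T≡U, case-insensitive); insert residues have no
columns and cannot participate, so over a bridged range the comparison is
against the flanks alone. The `is_lookup` flag marks the reference row.
Filtering is display-level only — it never recomputes counts — and matches
a literal, case-insensitive substring in which gap characters count, so a
gapless pattern excludes gapped variants.

Serialization: JSON carries a schema version, the query echo (units string,
limits, resolved intervals) and both tables without pagination; TSV carries
the details table; FASTA/Clustal carry the sub-alignment of extracted
columns with per-range blocks concatenated, since those formats cannot
represent the comma separator. The JSON field names are this package's own
schema, versioned via `schema_version`.

## I/O conventions

Gap characters `.` and `~` are normalized to `-` on input (normalization is
idempotent); residue letters are uppercased. `T` is preserved as written —
DNA-alphabet database entries are common for rRNA — and every sequence
comparison treats T≡U instead. The metadata join key is the sequence ID
(the FASTA header's first token); sequences without metadata keep empty
fields rather than being dropped. The Clustal conservation line is ignored
on input and omitted on output; nothing consumes it.

## The synthetic-data generator

`simulate_data_alignment(n, length, sub_rate, indel_rate, seed)` emulates a
curated alignment of n homologs: an ancestral sequence of the given length
is mutated independently per descendant, with each position substituted
with probability `sub_rate`, deleted with probability `indel_rate/2`, and
followed by a private 1–3 nt insertion with probability `indel_rate/2`.
Indels are applied at the alignment level — a deletion blanks a cell, an
insertion creates brand-new columns — so the natural-position→column truth
is exact bookkeeping, never inferred by realignment. The first sequence is
the unmutated ancestor and plays the lookup role, emulating the common case
of an exact database match for the structure's species.

`make_structure_variant` derives the structure chain from the lookup
sequence the way crystallized constructs differ from database entries: an
`insert_span` of the biological sequence may be replaced by an engineered
`insert_seq` (UNMAPPED in the truth table), a disjoint `missing_span` may
be absent entirely, and an optional polymer-index span receives
insertion-code numbering (each residue keeps the preceding number with
codes A, B, C, …), mirroring chains numbered to match a homolog.

Defaults used throughout the tests are 20 sequences × 120 positions at 5%
substitutions and 2% indels — small enough to inspect, dense enough that
generated alignments contain gapped columns, private insertions and
multiple distinct variants per query. The oracle-equivalence suite draws
100 fixtures of 20–50 sequences × 100–300 positions with randomized insert
and missing spans and checks every residue's mapped column and every
extracted variant against the truth tables exactly; the acceptance script
probes the validator on a 100-residue identity chain.

What the generator does *not* emulate: phylogenetic correlation between
sequences (mutations are i.i.d. per descendant), covariation imposed by
secondary structure, alignment error (truth is by construction), and
realistic rRNA length scales (desk-scale fixtures are two orders of
magnitude shorter than an SSU alignment). Passing tests therefore
demonstrate the correctness of the coordinate algebra and reporting on
alignments of arbitrary gap structure, not robustness to misalignment or
curation artifacts in real data.

## Numerical and degenerate-input choices

- Percent sums are validated to 100 ± 0.05·r for r summary rows (worst-case
  two-decimal rounding drift).
- An empty alignment, an empty units string, or a units item with a
  dangling colon is an error, never silently empty output.
- Duplicate sequence IDs and duplicate residue keys are rejected at parse
  time; later stages may assume uniqueness.
- Seeds: every generator function takes an explicit integer seed; identical
  seeds produce byte-identical fixture files.

## Known limitations

- The pairwise lookup alignment is consumed, not computed; constructing it
  well requires the 3D structure itself.
- One alignment per query; cross-molecule queries (e.g. SSU + LSU at once)
  are out of scope, as is any HTTP service, database backend, secondary-
  structure rendering or live database linking.
- Symmetry operators are carried through parsing and equality but are not
  expanded into coordinates; atom-level addressing is out of scope.
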