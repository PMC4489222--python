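# msamap

`msamap` translates residue-level addresses in RNA 3D structures into columns
of a curated multiple sequence alignment (MSA), extracts the addressed column
blocks, and summarizes the sequence variants found there. It is aimed at RNA
structural biologists and comparative-sequence analysts who want to ask, for a
motif seen in a crystal or cryo-EM structure — a basepair, a hairpin, an
internal loop — *what do the homologous positions look like across thousands
of aligned biological sequences?*

## The problem and the model

Structure files and sequence alignments speak different coordinate systems.
A structure chain is addressed by author residue numbers (possibly with
insertion codes, e.g. nucleotide `190L`), while an alignment is addressed by
column. `msamap` bridges them in two steps:

1. **Lookup alignment** (pairwise). The structure-derived sequence *S* is
   aligned to its closest database reference, the *lookup sequence* *R*. Each
   structure residue aligned to a residue of *R* receives that residue's
   *natural position* — its 1-based index in ungapped *R*. Structure residues
   aligned to gaps in *R* (engineered inserts such as crystallization
   hairpins, or otherwise unalignable residues) are **unmappable** and cannot
   serve as query endpoints.
2. **Data alignment** (the MSA). *R* is also a row of the curated MSA; its
   k-th non-gap character locates natural position k in an alignment column.

Composing the two strictly monotone maps takes a residue key
`(number, insertion_code)` through the chain's numbering table to a polymer
index i, then to natural position p = m₁(i), then to column c = m₂(p).
Queries are inclusive ranges of residues written as pipe-delimited Unit IDs
(`pdb|model|chain|identity|number|...|insertion_code`), at most 5 ranges and
at most 50 residues per range:

```
2AW7|1|A||1430:2AW7|1|A||1435,2AW7|1|A||1466:2AW7|1|A||1470
```

The extracted column intervals include interior columns where the lookup row
is gapped (insertions present only in other sequences), and a range may
*bridge* an engineered insert by choosing mapped endpoints on its flanks. An
endpoint without a natural position fails with "No data available in table".

Results are reported as a **Sequence Summary** (distinct variants with counts
and percentages of the total number of sequences) and a **Sequence Details**
table (one row per sequence: ID, extract, accession, taxonomy ID, organism,
lineage), with two highlight flags: `matches_structure` (the extract equals
the structure's own sequence over the query) and `is_lookup` (the reference
sequence used for the mapping). Output formats: JSON, TSV, gapped FASTA and
Clustal.

Because curated rRNA alignments are large hosted datasets, the package ships
a first-class generator (`msamap.fixtures`) that builds data/lookup alignment
pairs with exact, by-construction residue→column ground truth, including
engineered inserts, missing spans and insertion-code numbering runs.

## Worked example

Generate a demonstration registry (20 sequences × 120 reference positions,
5% substitutions, 2% indels, an engineered 9-nt insert replacing reference
positions 40–51 and a missing span at 60–63), then query an internal-loop
style pair of ranges:

```python
from msamap.fixtures import make_fixture_bundle
from msamap.registry import load_registry, run_query, select_alignment

bundle = make_fixture_bundle(
    "demo", n=20, length=120, sub_rate=0.05, indel_rate=0.02, seed=7,
    insert_span=(40, 51), insert_seq="GGGAAACCC", missing_span=(60, 63),
)
loaded = select_alignment(load_registry(bundle.config_path), "2AW7").load()
res = run_query(loaded, "2AW7|1|A||10:2AW7|1|A||15,2AW7|1|A||20")
for s in res.summary[:3]:
    print(f"{s.variant!r}  count={s.count}  percent={s.percent_str}")
```

prints

```
'AA--U---U---AC, C'  count=12  percent=60.00
'-A--U---UGCAAC, C'  count=1  percent=5.00
'AA--U---U----C, C'  count=1  percent=5.00
```

Residues 10–15 of chain A span 14 alignment columns (other sequences carry
insertions there, shown as `-` in the majority variant); the second range is
the single residue 20. The two range extracts are joined with `", "`. The
majority variant occurs in 12 of the 20 sequences (60.00%) and carries the
`matches_structure` flag because it equals the structure's own sequence over
the query. The same query via the CLI:

```bash
$ msamap list --registry demo/registry.yaml
2AW7    1       A       SSU rRNA        ssu-mini
$ msamap validate --registry demo/registry.yaml \
    --units "2AW7|1|A||10:2AW7|1|A||15,2AW7|1|A||20"
OK: 2 range(s), spans 6,1
$ msamap query --registry demo/registry.yaml \
    --units "2AW7|1|A||10:2AW7|1|A||15,2AW7|1|A||20" --format json --out out.json
$ msamap validate --registry demo/registry.yaml \
    --units "2AW7|1|A||1:2AW7|1|A||51"
RANGE_TOO_LONG: range spans 51 residues; at most 50 allowed   # exit code 3
```

Re-running the same units string against the same registry reproduces the
output byte for byte, so a saved query string is a durable record of a
result.

## Layout

- `msamap.unitid` — Unit ID grammar, query-equality, `units=` range strings
- `msamap.alnio` — gapped FASTA/Clustal I/O, numbering sidecars, metadata TSV
- `msamap.mapping` — residue→natural-position and natural-position→column maps
- `msamap.query` — limit validation, column resolution, extraction
- `msamap.report` — variant summary, detail rows, flags, filters, serialization
- `msamap.registry` / `msamap.cli` — structure→alignment registry and the CLI
- `msamap.fixtures` — synthetic alignment pairs with exact ground truth

See `docs/methods.md` for the mapping semantics, generator model and design
choices in detail.
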