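# Methods

This note documents the modeling decisions behind schemakit: the
semantics the kernel implements, the defaults and why they were chosen,
what the synthetic data does and does not emulate, and the known
limitations. It describes behavior the test suite actually exercises.

## The metamodel

Schemas are containers of four element categories — classes, slots,
types, enumerations — plus a prefix map and an import list. Two small
formal languages sit underneath everything:

**CURIEs.** An identifier is either a full URI (recognized by `://` or a
`urn:` prefix) or a compact `prefix:local` pair. Prefixes match
`[A-Za-z][A-Za-z0-9_.-]*`; everything after the first colon is the local
part, which may be digits only (`MIXS:0000009`) — common in ontology
namespaces. Expansion is concatenation against the registered base and
is idempotent on full URIs. Contraction is total: the longest matching
base wins, and a no-match returns the input with a `False` flag rather
than raising. Strictness is a call-site flag (default strict): strict
expansion raises on unknown prefixes, lax warns and passes the CURIE
through — validation contexts need hard failure, ingestion needs
tolerance.

**Cardinality.** The multiplicity grammar is `n`, `n..m`, `n..*`, with
`(0, 1)` the default when nothing is stated. Two typographic variants of
the separator — the two-dot leader `‥` and the ellipsis `…` — are
normalized to `..` before parsing, because spreadsheet exports produce
them in the wild. A bare `0` is rejected (it would describe a slot that
can never hold a value), as is `min > max`.

## Three-state slot flags

`required`, `multivalued` and `identifier` are `None` when an author did
not state them, not `False`. The distinction drives two behaviors:
field-wise inheritance (an unset field defers to the parent definition)
and faithful round-tripping of authored documents. Effective defaults
(false) are applied at compilation, never at parse time. `identifier`
implies `required` in the induced view.

## Inheritance compilation

`class_ancestors` linearizes `[self] + is_a-chain + mixins` depth-first
left-to-right with first-occurrence deduplication, so the
single-inheritance backbone wins ties on diamonds. Mixin semantics are
an open design surface in this style of modeling language; resolving
them *after* the `is_a` chain is this package's choice and is the
extension point to revisit if mixin-heavy models appear.

Induced-slot resolution is field-wise with nearest-wins precedence:
`slot_usage` in the class itself, then `slot_usage` in nearer ancestors,
then the nearest `attributes` declaration or the schema-level slot
definition. Slot order is root-most-ancestor slots first, then the
class's own — so a subclass reads as "everything general, then the
specialization". Each induced slot carries a provenance list of
(class, field, construct) records for every populated field, which the
documentation generator surfaces as "inherited from". A class may induce
at most one identifier slot; inheriting a second is an error, because
identifier minting and uniqueness checking need an unambiguous key.

`materialize` aggregates *all* dangling references into one error
instead of failing fast: schema authors fix batches, not single lines.

## Validation

All data problems are located issues in a report; the only exception a
caller can see is an unknown class name. Checks per induced slot:
required-present, list-shape ⇔ multivalued, scalar type conformance,
enum membership, anchored (full-match) regex patterns, recursion into
class-ranged values, and unknown-slot handling (closed-world ERROR by
default, WARNING under `--open-world`).

Numerical/textual tolerances, deliberately asymmetric:

* integers are accepted where a float is expected — spreadsheets store
  `30` for `30.0` — but nothing else coerces: `"37.87"` is not a number,
  and booleans are not integers;
* the empty string means "value absent", flagged only when the slot is
  required; this matches the empty-cell ambiguity of real spreadsheets,
  where blank cannot be distinguished from deliberately unspecified;
* enum matching is exact text, case-sensitive unless the enum opts into
  `case_insensitive` — permissible values are controlled vocabulary, not
  free text.

Validation engines are pluggable: `(name, prepare(ms, class) -> artifact,
check(artifact, doc) -> bool)`. Two engines ship — the native one and one
that evaluates the *generated* JSON Schema with the `jsonschema` library.
Their agreement on random conformant and deliberately corrupted documents
is a standing test. Known, enumerated expressiveness gaps excluded from
that comparison: identifier uniqueness (collection-level, outside JSON
Schema), `date`/`datetime` conformance (format annotations are
non-asserting in draft 2020-12), case-insensitive enums, and the
empty-string-as-absent policy on optional slots.

## Generators

JSON Schema output pins draft 2020-12 so goldens are stable. Every class
becomes a `$defs` object built from induced slots; `additionalProperties`
mirrors the closed/open flag; required string-typed slots get
`minLength: 1` to mirror the validator's empty-cell policy; `uri` and
`uriorcurie` ranges get patterns mirroring the native syntax checks.
Markdown docs emit one page per element plus an index and a plain-text
diagram edge list (`(Sample)-[environment_type]->(EnvironmentTypeEnum)`,
`(Sub)-[is_a]->(Base)`). SQL DDL emits one table per non-abstract class:
identifier slot as PRIMARY KEY (surrogate `<table>_pk` synthesized, with
a warning, when absent), `NOT NULL` for required, `CHECK (col IN (...))`
for enum ranges, and an auxiliary `(owner_id, value)` link table per
multivalued slot. Table/column names are snake_case transliterations with
the mapping recorded.

Every generator ships a machine-readable **loss report** alongside its
artifact, enumerating what the target formalism could not express.
Conversions lose information; the loss should be data, not folklore.

## Tabular authoring and inference

The directive row maps spreadsheet columns to metamodel fields
(`class slot cardinality required range is_a description`). A row with
only a class cell declares a class; a row with both attaches a slot.
Classes referenced by slot rows but never declared get created
implicitly (real sheets skip the boilerplate row); export always writes
the explicit class row. The cardinality/required interplay: min ≥ 1
implies required; pairing `0..1` with required TRUE is *accepted* (the
required column wins, multiplicity governs multivaluedness) because
authored sheets do exactly that; only min ≥ 1 against an explicit FALSE
is a hard conflict. The conversion result retains the parsed
multiplicity per (class, slot), since the converted flags alone cannot
reconstruct it.

Inference defaults: a non-numeric column becomes an enum when it has at
most 10 distinct values and ≥ 1.5 rows per value; a slot is required when
under 10% of its cells are blank. No standard heuristic exists for
these; the values are configurable (`InferenceOptions`) and chosen so
that a handful of repeated category labels infers an enum but free text
does not. Enum values are sorted, making inference order-insensitive.

## Transformations

Specs are ordered operation lists (rename, split, merge, retype,
recardinalize, subset) applied coherently to schema and data, with an
audit trail. Split is exact-arity with trimming and no regex delimiters:
a two-target split of `"37.87"` is an error, not a guess — dirty data
should surface, not slip through. A missing source value propagates
absence to all targets, matching the validator's empty-cell policy.
Specs are schema-level only (no per-row conditionals); conditionals are
a deliberate extension point.

## Synthetic data: what it emulates, and what it does not

The messy-table generator emulates the failure modes the toolkit exists
to fix: depth in mixed unit dialects (`1622.5 cm`, `2.1m`, `3 meters`,
bare numbers), fused `lat, lon` position cells, vocabulary terms with
case noise and synonyms, blank cells, and unparseable garbage — each
injected independently per cell at configurable rates (defaults 0, i.e.
clean), with at most one fault per cell and the full fault inventory
retained as ground truth.

Only decimal metric dialects (m, cm, mm) are *emitted*, so that
harmonization of unfaulted cells is exactly lossless at 3-decimal
rounding; the harmonizer's unit table nevertheless understands ft/in for
externally supplied data. The generator does not emulate: encoding
corruption, locale decimal commas, merged or shifted columns, duplicate
rows, or adversarial near-miss vocabulary ("soill"). Passing the
recovery tests therefore shows the pipeline is correct on the stated
fault classes, not that it is robust to arbitrary real spreadsheets.

Harmonization is total: every cell lands in the provenance log
(minted / converted / split / matched / case_folded / synonym_mapped /
blank_absent / rejected), every rejection is a located report issue, and
rows partition exactly into clean and rejected. Identifier minting
(`<prefix>:<4-digit ordinal>`) is a fixture policy. Repairable faults
(case, synonym) are repaired and hence produce no issues; the
one-issue-per-fault accounting holds for the unrepairable kinds, and a
blanked fused position cell yields two issues (both coordinate slots go
missing) by construction.

## Problem sizes and numerical choices

The property suites run at deliberately small scale — ≤ 8-class random
hierarchies against brute-force linearization oracles, 100 random
schemas per round-trip identity, 110+ documents per dual-route
equivalence class, 150-row fault-injection tables — sizes at which the
oracles stay trivially checkable while covering the combinatorics.
Depth conversion rounds to 3 decimals (millimetre resolution); unit
round-trips are stable to 1e-9. All randomness is seeded; regeneration
is byte-identical for equal inputs, and generator/emitters order output
deterministically (insertion order of the source schema, fixed key
order in YAML/JSON).

## Known limitations

No RDF/OWL/SHACL/ShEx emission and no native-code class generation;
prefix maps are local and explicit (no registry resolution); imports are
resolved from a configured search path, never fetched; no cross-document
referential integrity beyond identifier uniqueness; no fuzzy or
ML-based term matching in harmonization; boolean-expression slot
constraints are out of scope.
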