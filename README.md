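# schemakit

A self-contained schema-modeling kernel for FAIR scientific metadata.

Much scientific data lives in spreadsheets whose meaning is implicit: a
column called `dep` with cells like `30 cm`, `1.2m` and `4 meters`; a fused
`position` cell holding `"37.87, -122.27"`; free-text environment labels
("Soil", "dirt", "seawater") that cannot be compared across studies.
schemakit is for the people who have to fix that — data managers, curators
and research software engineers — and gives them one explicit, computable
schema from which everything else is derived: validation, documentation,
JSON Schema, SQL DDL, and controlled migrations when the model evolves.

## The model

A schema is built from four element categories:

* **classes** — conceptual entities (`Sample`, `Study`), arranged in
  hierarchies (`AirSampleSite is_a SampleSite`) with single-inheritance
  `is_a` backbones plus mixins;
* **slots** — attributes of classes, each with a *range*, cardinality
  flags (`required`, `multivalued`, `identifier`), an optional regex
  pattern, a unit label, and URI/ontology mappings;
* **types** — primitive value spaces (`string`, `integer`, `float`,
  `boolean`, `uri`, `uriorcurie`, `date`, `datetime`) plus user types;
* **enumerations** — controlled vocabularies whose permissible values can
  carry an ontology *meaning* CURIE (e.g. `soil -> ENVO:00001998`).

Cardinality follows the standard multiplicity grammar: `0..1` optional,
`1` required, `0..*` zero or more (so for a slot, min ≥ 1 ⇔ required and
max > 1 ⇔ multivalued). Identifiers are compact URIs (`prefix:local`)
expanded against an explicit prefix map; contraction picks the longest
matching base.

The *compiler* materializes each class's **induced slots**: the effective
definitions after walking the ancestry and applying `slot_usage`
overrides with nearest-wins, field-wise precedence. Every downstream
component — validator, generators, exporters — consumes that induced view
rather than re-implementing inheritance.

## Worked example

Generate a deliberately messy sample table and harmonize it against the
bundled microbiome `Sample` schema (required `latitude`/`longitude`
floats, optional `depth` in metres, an ENVO-aligned environment
vocabulary, CURIE identifiers):

```python
from schemakit.fixtures import (
    generate_messy_samples, harmonize_samples, sample_schema_materialized,
)

table = generate_messy_samples(
    seed=7, n_rows=12, fault_rates={"blank": 0.1, "synonym": 0.3, "case": 0.3}
)
print(table.rows[0])   # ['-62.8471, 54.3364', '1622.5 cm', '']
print(table.rows[1])   # ['-46.6807, 18.377', '2093.8 cm', 'soil']

result = harmonize_samples(table, sample_schema_materialized())
print(result.clean_docs[0].values)
# {'id': 'samp:0001', 'depth': 16.225, 'latitude': -62.8471, 'longitude': 54.3364}
```

`1622.5 cm` became `16.225` (metres, 3 decimals), the fused position cell
was split through the declarative transformation engine, a zero-padded
CURIE identifier was minted, and the blanked environment cell was simply
left absent (the slot is optional). Every cell action is recorded in
`result.provenance`; unparseable cells become located issues in
`result.report` and the row is emitted without that slot.

The same machinery is available from the shell:

```console
$ schemakit demo-harmonize --seed 7 --rows 12
12 rows -> 12 clean, 0 rejected, 0 issue(s)

$ schemakit validate -s sample.yaml -d bad.json -C Sample
ERROR [required_missing] /latitude: required slot 'latitude' is missing or empty
ERROR [enum_miss] /environment_type: value not among permissible values of EnvironmentTypeEnum: ['soil', 'water', 'air', 'sediment']
2 error(s), 0 warning(s)
```

Other subcommands cover the rest of the lifecycle: `sheet2schema` /
`schema2sheet` (directive-row spreadsheet authoring), `infer` (bootstrap
a schema from raw data), `lint` (naming conventions, descriptions,
ranges), `gen-json-schema` / `gen-docs` / `gen-sql` (derived artifacts,
each with a machine-readable loss report), `map` (declarative
rename/split/merge/subset migrations applied to schema and data
together), and `dump-induced` (the compiled inheritance view).

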