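import json
import random
import sqlite3

import jsonschema
import pytest

from schemakit.fixtures import corrupt_document, random_documents
from schemakit.compiler import materialize
from schemakit.generators import (
    gen_json_schema,
    gen_markdown_docs,
    gen_sql_ddl,
    snake_case,
)
from schemakit.schema_io import parse_schema
from schemakit.validator import JsonSchemaEngine, NativeEngine


def _schema_doc(artifact):
    text = next(c for n, c in artifact.files.items()
                if n.endswith(".schema.json"))
    return json.loads(text)


def _loss_doc(artifact):
    text = next(c for n, c in artifact.files.items() if ".loss." in n)
    return json.loads(text)


class TestJsonSchema:
    def test_sample_class_shape(self, ms):
        doc = _schema_doc(gen_json_schema(ms, "Sample"))
        assert doc["$schema"] == "https://json-schema.org/draft/2020-12/schema"
        sample = doc["$defs"]["Sample"]
        assert set(sample["properties"]) == {
            "id", "latitude", "longitude", "depth", "environment_type",
        }
        assert set(sample["required"]) == {"id", "latitude", "longitude"}
        assert sample["properties"]["latitude"] == {"type": "number"}
        assert sample["properties"]["environment_type"] == {
            "enum": ["soil", "water", "air", "sediment"]
        }
        assert sample["additionalProperties"] is False
        # multivalued class-ranged slot becomes an array of references
        study = doc["$defs"]["Study"]
        assert study["properties"]["samples"] == {
            "type": "array", "items": {"$ref": "#/$defs/Sample"},
        }

    def test_empty_class_yields_empty_properties(self):
        m = materialize(parse_schema(
            "id: https://x/s\nname: s\nclasses:\n  Empty: {}\n"
        ))
        doc = _schema_doc(gen_json_schema(m, "Empty"))
        assert doc["$defs"]["Empty"]["properties"] == {}

    def test_loss_report_enumerates_identifier_uniqueness(self, ms):
        losses = _loss_doc(gen_json_schema(ms, "Sample"))["losses"]
        codes = {(l["code"], l["element"]) for l in losses}
        assert ("identifier_uniqueness", "Sample") in codes
        assert ("identifier_uniqueness", "Study") in codes

    def test_generated_schema_is_itself_valid(self, ms):
        doc = _schema_doc(gen_json_schema(ms, "Sample"))
        jsonschema.Draft202012Validator.check_schema(doc)

    @pytest.mark.parametrize("class_name", ["Sample", "Study"])
    def test_oracle_equivalence_native_vs_json_schema(self, ms, class_name):
        """Both validation routes classify 100+ random docs identically.

        Identifier uniqueness is a collection-level check JSON Schema
        cannot express; only single-document validity is compared.
        """
        rng = random.Random(11)
        native, jse = NativeEngine(), JsonSchemaEngine()
        a_native = native.prepare(ms, class_name)
        a_json = jse.prepare(ms, class_name)
        docs = random_documents(ms, class_name, 60, rng)
        cases = [(d, True) for d in docs]
        for d in docs:
            corrupted, _ = corrupt_document(ms, d, rng)
            cases.append((corrupted, False))
        assert len(cases) >= 100
        for document, expected_valid in cases:
            v_native = native.check(a_native, document)
            v_json = jse.check(a_json, document)
            assert v_native == v_json == expected_valid


class TestMarkdownDocs:
    def test_every_element_on_exactly_one_page_and_indexed(self, ms):
        art = gen_markdown_docs(ms)
        pages = set(art.files)
        elements = (
            set(ms.source.classes) | set(ms.source.enums)
            | set(ms.source.types) | set(ms.source.slots)
            | {s for c in ms.source.classes.values() for s in c.attributes}
        )
        for element in elements:
            assert f"{element}.md" in pages
        index = art.files["index.md"]
        for element in elements:
            assert f"[{element}]({element}.md)" in index

    def test_class_page_lists_induced_slots_with_cardinality(self, ms):
        page = gen_markdown_docs(ms).files["Sample.md"]
        assert "| latitude | 1 | float |" in page
        assert "| environment_type | 0..1 | EnvironmentTypeEnum |" in page

    def test_diagram_edge_list(self, ms):
        diagram = gen_markdown_docs(ms).files["schema_diagram.txt"]
        assert "(Sample)-[environment_type]->(EnvironmentTypeEnum)" in diagram
        assert "(Study)-[samples]->(Sample)" in diagram

    def test_inheritance_edge_present(self):
        m = materialize(parse_schema(
            "id: https://x/s\nname: s\ndefault_range: string\n"
            "classes:\n  Base: {}\n  Sub: {is_a: Base}\n"
        ))
        assert "(Sub)-[is_a]->(Base)" in \
            gen_markdown_docs(m).files["schema_diagram.txt"]

    def test_empty_schema_yields_index_only(self):
        m = materialize(parse_schema("id: https://x/s\nname: s\n"))
        art = gen_markdown_docs(m)
        assert set(art.files) == {"index.md", "schema_diagram.txt"}

    def test_regeneration_is_byte_identical(self, ms):
        assert gen_markdown_docs(ms).files == gen_markdown_docs(ms).files


class TestSqlDdl:
    def test_ddl_loads_and_round_trips_a_record(self, ms):
        ddl = gen_sql_ddl(ms).files["sample_schema.sql"]
        con = sqlite3.connect(":memory:")
        con.executescript(ddl)
        row = ("samp:0001", 37.87, -122.27, 0.3, "soil")
        con.execute(
            "INSERT INTO sample (id, latitude, longitude, depth, "
            "environment_type) VALUES (?,?,?,?,?)", row,
        )
        assert con.execute("SELECT * FROM sample").fetchone() == row

    def test_identifier_becomes_primary_key_and_required_not_null(self, ms):
        ddl = gen_sql_ddl(ms).files["sample_schema.sql"]
        assert "id TEXT PRIMARY KEY" in ddl
        assert "latitude REAL NOT NULL" in ddl

    def test_enum_check_constraint_enforced(self, ms):
        con = sqlite3.connect(":memory:")
        con.executescript(gen_sql_ddl(ms).files["sample_schema.sql"])
        with pytest.raises(sqlite3.IntegrityError):
            con.execute(
                "INSERT INTO sample (id, latitude, longitude, "
                "environment_type) VALUES ('samp:2', 0, 0, 'lava')"
            )

    def test_abstract_class_gets_no_table(self):
        m = materialize(parse_schema(
            "id: https://x/s\nname: abstracted\ndefault_range: string\n"
            "classes:\n"
            "  Base: {abstract: true}\n"
            "  Concrete: {is_a: Base}\n"
        ))
        ddl = gen_sql_ddl(m).files["abstracted.sql"]
        assert "CREATE TABLE concrete" in ddl
        assert "CREATE TABLE base" not in ddl

    def test_missing_identifier_synthesizes_surrogate_key(self):
        m = materialize(parse_schema(
            "id: https://x/s\nname: nokey\ndefault_range: string\n"
            "classes:\n  Thing:\n    attributes:\n      label: {}\n"
        ))
        art = gen_sql_ddl(m)
        assert "thing_pk INTEGER PRIMARY KEY" in art.files["nokey.sql"]
        losses = _loss_doc(art)["losses"]
        assert any(l["code"] == "no_identifier" for l in losses)

    def test_multivalued_slot_becomes_link_table(self, ms):
        ddl = gen_sql_ddl(ms).files["sample_schema.sql"]
        assert "CREATE TABLE study_samples" in ddl
        assert "study_id TEXT NOT NULL" in ddl


def test_snake_case_transliteration():
    assert snake_case("AirSampleSite") == "air_sample_site"
    assert snake_case("PM25Level") == "pm25_level"
    assert snake_case("environment_type") == "environment_type"
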