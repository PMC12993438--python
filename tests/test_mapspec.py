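import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from schemakit.compiler import materialize
from schemakit.errors import (
    CastError,
    SplitArityMismatch,
    TransformError,
    TransformReferenceError,
    UnknownOperationKind,
)
from schemakit.fixtures import (
    LEGACY_POSITION_SCHEMA_YAML,
    POSITION_SPLIT_SPEC_YAML,
    random_documents,
)
from schemakit.mapspec import (
    Merge,
    Rename,
    Split,
    TransformSpec,
    derive_schema,
    parse_transform_spec,
    transform_instance,
)
from schemakit.schema_io import parse_schema
from schemakit.validator import InstanceDocument, validate_instance


@pytest.fixture
def legacy():
    return parse_schema(LEGACY_POSITION_SCHEMA_YAML)


@pytest.fixture
def migration():
    return parse_transform_spec(POSITION_SPLIT_SPEC_YAML)


class TestParsing:
    def test_single_rename(self):
        spec = parse_transform_spec(
            "- op: rename\n  class: C\n  from: a\n  to: b\n"
        )
        assert spec.operations == [Rename("C", "a", "b")]

    def test_migration_fixture_is_two_operations(self, migration):
        kinds = [type(op).__name__ for op in migration.operations]
        assert kinds == ["Split", "Rename"]
        split = migration.operations[0]
        assert split.targets == ["latitude", "longitude"]
        assert split.target_ranges == ["float", "float"]

    def test_unknown_operation_kind(self):
        with pytest.raises(UnknownOperationKind):
            parse_transform_spec("- op: frobnicate\n  class: C\n")

    def test_missing_fields_rejected(self):
        with pytest.raises(TransformError):
            parse_transform_spec("- op: rename\n  class: C\n  from: a\n")

    def test_split_needs_two_targets(self):
        with pytest.raises(TransformError):
            parse_transform_spec(
                "- op: split\n  class: C\n  slot: x\n  targets: [only]\n"
            )


class TestDeriveSchema:
    def test_position_migration_reshapes_sample(self, legacy, migration):
        derived = derive_schema(legacy, migration).derived_schema
        attrs = derived.classes["Sample"].attributes
        assert "position" not in attrs
        assert {"latitude", "longitude", "sample_type"} <= set(attrs)
        assert attrs["latitude"].range == "float"
        # rename preserves every other slot field
        assert attrs["sample_type"].range == "EnvironmentTypeEnum"
        assert attrs["sample_type"].description == (
            "The environment from which the sample was taken."
        )
        materialize(derived)  # still referentially consistent

    def test_empty_spec_is_identity(self, legacy):
        assert derive_schema(legacy, TransformSpec()).derived_schema == legacy

    def test_subset_drops_class_with_audit(self, schema):
        spec = parse_transform_spec(
            "- op: subset\n  keep_classes: [Sample]\n"
        )
        result = derive_schema(schema, spec)
        assert list(result.derived_schema.classes) == ["Sample"]
        assert result.audit[0]["dropped_classes"] == ["Study"]

    def test_subset_prunes_slots_ranging_over_dropped_classes(self, schema):
        spec = parse_transform_spec("- op: subset\n  keep_classes: [Study]\n")
        derived = derive_schema(schema, spec).derived_schema
        assert "samples" not in derived.classes["Study"].attributes
        materialize(derived)

    def test_dangling_reference_names_operation(self, legacy):
        spec = parse_transform_spec(
            "- op: rename\n  class: Sample\n  from: ghost\n  to: g2\n"
        )
        with pytest.raises(TransformReferenceError) as exc:
            derive_schema(legacy, spec)
        assert exc.value.op_index == 0
        assert "ghost" in str(exc.value)


class TestTransformInstance:
    def test_split_casts_parts(self, migration):
        doc = InstanceDocument("Sample", {"position": "37.87, -122.27"})
        out = transform_instance(doc, migration)
        assert out.values == {"latitude": 37.87, "longitude": -122.27}

    def test_rename_relabels_key(self, migration):
        doc = InstanceDocument("Sample", {"environment_type": "soil"})
        out = transform_instance(doc, migration)
        assert out.values == {"sample_type": "soil"}

    def test_split_arity_mismatch(self, migration):
        doc = InstanceDocument("Sample", {"position": "37.87"})
        with pytest.raises(SplitArityMismatch):
            transform_instance(doc, migration)

    def test_split_cast_error(self, migration):
        doc = InstanceDocument("Sample", {"position": "north, south"})
        with pytest.raises(CastError):
            transform_instance(doc, migration)

    def test_missing_source_propagates_absence(self, migration):
        out = transform_instance(
            InstanceDocument("Sample", {"id": "samp:1"}), migration
        )
        assert out.values == {"id": "samp:1"}

    def test_untouched_slots_pass_through(self, migration):
        doc = InstanceDocument(
            "Sample",
            {"id": "samp:1", "position": "1, 2", "environment_type": "air"},
        )
        out = transform_instance(doc, migration)
        assert out.values["id"] == "samp:1"
        assert out.values["sample_type"] == "air"

    def test_merge_joins_sources(self):
        spec = TransformSpec([Merge("C", ["lat", "lon"], "position", ", ")])
        doc = InstanceDocument("C", {"lat": 1.5, "lon": 2.5})
        out = transform_instance(doc, spec)
        assert out.values == {"position": "1.5, 2.5"}


class TestProperties:
    @given(
        parts=st.lists(
            st.text(
                alphabet=st.characters(
                    blacklist_characters=",", blacklist_categories=("Cs", "Cc")
                ),
                min_size=1, max_size=8,
            ).map(str.strip).filter(bool),
            min_size=2, max_size=4,
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_split_then_merge_recovers_source(self, parts):
        """Splitting and re-merging with one delimiter is the identity
        (up to whitespace trimming, which the filter already applies)."""
        n = len(parts)
        targets = [f"t{i}" for i in range(n)]
        spec = TransformSpec([
            Split("C", "src", targets, delimiter=","),
            Merge("C", targets, "src", delimiter=","),
        ])
        source = ",".join(parts)
        out = transform_instance(InstanceDocument("C", {"src": source}), spec)
        assert out.values == {"src": ",".join(p.strip() for p in parts)}

    def test_migrated_random_documents_validate_against_derived_schema(
        self, legacy, migration
    ):
        source_ms = materialize(legacy)
        derived_ms = materialize(
            derive_schema(legacy, migration).derived_schema
        )
        rng = random.Random(31)
        docs = random_documents(source_ms, "Sample", 100, rng)
        for doc in docs:
            # the fused field gets a well-formed "lat, lon" payload
            doc.values["position"] = (
                f"{round(rng.uniform(-90, 90), 4)}, "
                f"{round(rng.uniform(-180, 180), 4)}"
            )
            assert validate_instance(source_ms, doc).valid
            migrated = transform_instance(doc, migration, source_ms)
            report = validate_instance(derived_ms, migrated)
            assert report.valid, report.to_text()

    def test_operation_order_is_respected(self):
        schema = parse_schema(
            "id: https://x/s\nname: s\ndefault_range: string\n"
            "classes:\n  C:\n    attributes:\n      a: {range: string}\n"
        )
        rename_then_split = parse_transform_spec(
            "- {op: rename, class: C, from: a, to: b}\n"
            "- {op: split, class: C, slot: b, targets: [x, y]}\n"
        )
        split_then_rename = parse_transform_spec(
            "- {op: split, class: C, slot: a, targets: [x, y]}\n"
            "- {op: rename, class: C, from: a, to: b}\n"
        )
        derived = derive_schema(schema, rename_then_split).derived_schema
        assert set(derived.classes["C"].attributes) == {"x", "y"}
        with pytest.raises(TransformReferenceError):
            derive_schema(schema, split_then_rename)
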