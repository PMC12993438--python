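import random

import pytest

from schemakit.compiler import class_ancestors, induced_slots, materialize
from schemakit.errors import (
    ConflictingIdentifier,
    CycleDetected,
    IntegrityError,
    UnknownClass,
)
from schemakit.schema_io import (
    ClassDefinition,
    SchemaDefinition,
    SlotDefinition,
    parse_schema,
)

SITE_SCHEMA = """\
id: https://example.org/sites
name: sites
default_range: string
classes:
  SampleSite:
    description: A generic sampling location.
    attributes:
      site_id: {identifier: true, required: true, range: string}
      name: {range: string}
  AirSampleSite:
    description: A sampling location for air samples.
    is_a: SampleSite
    attributes:
      humidity: {range: float}
      pm2_5_level: {range: float}
"""


def _blank_schema(**classes):
    schema = SchemaDefinition(id="https://example.org/h", name="h")
    schema.classes.update(classes)
    return schema


class TestAncestry:
    def test_subclass_chain(self):
        schema = parse_schema(SITE_SCHEMA)
        assert class_ancestors(schema, "AirSampleSite") == [
            "AirSampleSite", "SampleSite",
        ]

    def test_root_class_is_its_own_ancestry(self):
        schema = parse_schema(SITE_SCHEMA)
        assert class_ancestors(schema, "SampleSite") == ["SampleSite"]

    def test_unknown_class(self):
        with pytest.raises(UnknownClass):
            class_ancestors(parse_schema(SITE_SCHEMA), "Nope")

    def test_cycle_detected(self):
        schema = _blank_schema(
            A=ClassDefinition(name="A", is_a="B"),
            B=ClassDefinition(name="B", is_a="A"),
        )
        with pytest.raises(CycleDetected):
            class_ancestors(schema, "A")

    def test_random_hierarchies_match_naive_linearization(self):
        # independent oracle: plain recursive expansion (self, is_a chain,
        # then mixins depth-first), dedup keeping first occurrence
        def naive(schema, name, seen=None):
            order = [name]
            cls = schema.classes[name]
            for parent in ([cls.is_a] if cls.is_a else []) + list(cls.mixins):
                order.extend(naive(schema, parent))
            out = []
            for n in order:
                if n not in out:
                    out.append(n)
            return out

        rng = random.Random(77)
        for _ in range(200):
            n = rng.randint(1, 8)
            schema = _blank_schema()
            names = [f"C{i}" for i in range(n)]
            for i, name in enumerate(names):
                cls = ClassDefinition(name=name)
                if i > 0 and rng.random() < 0.7:
                    cls.is_a = rng.choice(names[:i])
                pool = [m for m in names[:i] if m != cls.is_a]
                rng.shuffle(pool)
                cls.mixins = pool[: rng.randint(0, min(2, len(pool)))]
                schema.classes[name] = cls
            target = rng.choice(names)
            assert class_ancestors(schema, target) == naive(schema, target)


class TestInducedSlots:
    def test_inherited_slots_come_first_root_most(self):
        schema = parse_schema(SITE_SCHEMA)
        names = [s.name for s in induced_slots(schema, "AirSampleSite")]
        assert names == ["site_id", "name", "humidity", "pm2_5_level"]

    def test_slot_usage_tightens_inherited_slot(self):
        schema = parse_schema(
            "id: https://x/s\nname: s\ndefault_range: string\n"
            "classes:\n"
            "  Base:\n    attributes:\n      note: {range: string}\n"
            "  Strict:\n    is_a: Base\n"
            "    slot_usage:\n      note: {required: true}\n"
        )
        slots = {s.name: s for s in induced_slots(schema, "Strict")}
        assert slots["note"].required is True
        assert ("Strict", "required", "slot_usage") in slots["note"].provenance
        # the base class is untouched
        base = {s.name: s for s in induced_slots(schema, "Base")}
        assert not base["note"].required

    def test_nearest_usage_wins_over_farther(self):
        schema = parse_schema(
            "id: https://x/s\nname: s\ndefault_range: string\n"
            "classes:\n"
            "  A:\n    attributes:\n      v: {range: string}\n"
            "  B:\n    is_a: A\n    slot_usage:\n      v: {range: integer}\n"
            "  C:\n    is_a: B\n    slot_usage:\n      v: {range: float}\n"
        )
        slots = {s.name: s for s in induced_slots(schema, "C")}
        assert slots["v"].definition.range == "float"

    def test_class_with_no_slots(self):
        schema = _blank_schema(Empty=ClassDefinition(name="Empty"))
        assert induced_slots(schema, "Empty") == []

    def test_conflicting_identifiers_rejected(self):
        schema = parse_schema(
            "id: https://x/s\nname: s\ndefault_range: string\n"
            "classes:\n"
            "  Base:\n    attributes:\n      pk1: {identifier: true}\n"
            "  Sub:\n    is_a: Base\n"
            "    attributes:\n      pk2: {identifier: true}\n"
        )
        with pytest.raises(ConflictingIdentifier):
            induced_slots(schema, "Sub")

    def test_identifier_implies_required(self):
        schema = parse_schema(
            "id: https://x/s\nname: s\ndefault_range: string\n"
            "classes:\n  C:\n    attributes:\n      id: {identifier: true}\n"
        )
        slots = {s.name: s for s in induced_slots(schema, "C")}
        assert slots["id"].required

    def test_random_hierarchies_match_brute_force_override_walk(self):
        # oracle: walk ancestors root-most -> self, naively overlaying
        # attribute definitions then slot_usage refinements
        def naive_induced(schema, cname):
            chain = list(reversed(class_ancestors(schema, cname)))
            result: dict[str, dict] = {}
            for c in chain:
                for sname, slot in schema.classes[c].attributes.items():
                    entry = result.setdefault(sname, {})
                    for f in ("range", "required", "multivalued"):
                        if getattr(slot, f) is not None:
                            entry[f] = getattr(slot, f)
            for c in chain:
                for sname, usage in schema.classes[c].slot_usage.items():
                    if sname not in result:
                        continue
                    for f in ("range", "required", "multivalued"):
                        if getattr(usage, f) is not None:
                            result[sname][f] = getattr(usage, f)
            return result

        rng = random.Random(123)
        for _ in range(100):
            schema = _blank_schema()
            names = [f"C{i}" for i in range(rng.randint(1, 6))]
            slot_pool = [f"s{i}" for i in range(5)]
            for i, name in enumerate(names):
                cls = ClassDefinition(name=name)
                if i > 0 and rng.random() < 0.7:
                    cls.is_a = rng.choice(names[:i])
                for sname in rng.sample(slot_pool, rng.randint(0, 3)):
                    cls.attributes[sname] = SlotDefinition(
                        name=sname,
                        range=rng.choice(["string", "integer", "float"]),
                        required=rng.choice([None, True, False]),
                    )
                schema.classes[name] = cls
            for name in names:  # random usage refinements on known slots
                cls = schema.classes[name]
                chain = list(reversed(class_ancestors(schema, name)))
                visible = {
                    s for c in chain for s in schema.classes[c].attributes
                }
                for sname in visible:
                    if rng.random() < 0.2:
                        cls.slot_usage[sname] = SlotDefinition(
                            name=sname, required=rng.choice([True, False])
                        )
            for name in names:
                got = {
                    s.name: {
                        f: getattr(s.definition, f)
                        for f in ("range", "required", "multivalued")
                        if getattr(s.definition, f) is not None
                    }
                    for s in induced_slots(schema, name)
                }
                assert got == naive_induced(schema, name)


class TestMaterialize:
    def test_sample_schema_materializes(self, ms):
        assert [s.name for s in ms.induced["Sample"]] == [
            "id", "latitude", "longitude", "depth", "environment_type",
        ]
        assert ms.identifier_slot == {"Sample": "id", "Study": "id"}
        assert ms.ancestry["Sample"] == ["Sample"]

    def test_dangling_range_reported_with_names(self):
        schema = parse_schema(
            "id: https://x/s\nname: s\n"
            "classes:\n  C:\n    attributes:\n"
            "      color: {range: MissingEnum}\n"
            "      size: {range: MissingType}\n"
        )
        with pytest.raises(IntegrityError) as exc:
            materialize(schema)
        text = str(exc.value)
        # every dangling reference is aggregated, not just the first
        assert "MissingEnum" in text and "MissingType" in text
        assert "color" in text and "size" in text

    def test_materialization_idempotent(self, ms):
        again = materialize(ms.source)
        assert again.ancestry == ms.ancestry
        assert again.identifier_slot == ms.identifier_slot
        assert {
            c: [s.definition for s in slots] for c, slots in again.induced.items()
        } == {
            c: [s.definition for s in slots] for c, slots in ms.induced.items()
        }

    def test_adding_ancestor_slot_is_monotone(self):
        text = (
            "id: https://x/s\nname: s\ndefault_range: string\n"
            "classes:\n"
            "  Base:\n    attributes:\n      a: {range: string}\n"
            "  Sub:\n    is_a: Base\n    attributes:\n      b: {range: string}\n"
        )
        schema = parse_schema(text)
        before = {s.name for s in induced_slots(schema, "Sub")}
        schema.classes["Base"].attributes["c"] = SlotDefinition(
            name="c", range="string"
        )
        after = {s.name for s in induced_slots(schema, "Sub")}
        assert before <= after and "c" in after
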