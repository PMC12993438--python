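import random

import pytest

from schemakit.compiler import materialize
from schemakit.fixtures import sample_schema, sample_schema_materialized
from schemakit.metamodel import Mapping
from schemakit.schema_io import (
    ClassDefinition,
    EnumDefinition,
    PermissibleValue,
    SchemaDefinition,
    SlotDefinition,
)

PRIMITIVES = ["string", "integer", "float", "boolean", "uriorcurie"]


@pytest.fixture
def schema():
    return sample_schema()


@pytest.fixture
def ms():
    return sample_schema_materialized()


def random_slot(rng: random.Random, name: str, ranges: list[str],
                rich: bool = True) -> SlotDefinition:
    slot = SlotDefinition(name=name)
    if rng.random() < 0.8:
        slot.description = f"Slot {name}."
    slot.range = rng.choice(ranges) if rng.random() < 0.9 else None
    for flag in ("required", "multivalued"):
        if rng.random() < 0.5:
            setattr(slot, flag, rng.random() < 0.5)
    if rich:
        if rng.random() < 0.2 and slot.range == "string":
            slot.pattern = "[a-z]+"
        if rng.random() < 0.2:
            slot.slot_uri = f"ex:{name}"
        if rng.random() < 0.1:
            slot.unit = "m"
        if rng.random() < 0.2:
            slot.mappings = [Mapping("exact", f"ex:map_{name}")]
    return slot


def random_schema(rng: random.Random, max_classes: int = 4,
                  expressible_only: bool = False) -> SchemaDefinition:
    """Random schema; restricted to sheet-expressible features on demand."""
    schema = SchemaDefinition(
        id="https://example.org/random",
        name="random_schema",
    )
    if not expressible_only:
        schema.prefixes.bind("ex", "https://example.org/")
        if rng.random() < 0.5:
            schema.default_range = "string"
    ranges = list(PRIMITIVES)
    if not expressible_only and rng.random() < 0.6:
        n_pv = rng.randint(1, 4)
        schema.enums["ColorEnum"] = EnumDefinition(
            name="ColorEnum",
            description="Random colors.",
            permissible_values={
                f"col{i}": PermissibleValue(text=f"col{i}", meaning=f"ex:{i}")
                for i in range(n_pv)
            },
        )
        ranges.append("ColorEnum")
    class_names = [f"Klass{i}" for i in range(rng.randint(1, max_classes))]
    for i, cname in enumerate(class_names):
        cls = ClassDefinition(name=cname, description=f"Class {cname}.")
        if i > 0 and rng.random() < 0.5:
            cls.is_a = rng.choice(class_names[:i])
        if not expressible_only and rng.random() < 0.2:
            cls.abstract = True
        for j in range(rng.randint(0, 4)):
            sname = f"slot_{i}_{j}"
            cls.attributes[sname] = random_slot(
                rng, sname, ranges, rich=not expressible_only
            )
        schema.classes[cname] = cls
    if not expressible_only and class_names and rng.random() < 0.5:
        schema.slots["shared_slot"] = random_slot(rng, "shared_slot", ranges)
        target = rng.choice(class_names)
        schema.classes[target].slots.append("shared_slot")
    return schema


def assert_valid_hierarchy(schema: SchemaDefinition) -> bool:
    try:
        materialize(schema)
        return True
    except Exception:
        return False
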