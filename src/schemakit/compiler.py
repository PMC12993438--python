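"""Compile a schema into its induced view.

Class hierarchies let a schema define a general concept (a sample site)
and specialize it (an air sample site adding humidity or particulate
slots). Downstream consumers — validator, generators, exporters — should
never re-implement that inheritance walk, so this module materializes it
once: for every class, its linearized ancestry and the fully resolved
("induced") slot list after applying overrides.

Override precedence, nearest wins:

1. ``slot_usage`` in the class itself,
2. ``slot_usage`` in a nearer ancestor,
3. the nearest ``attributes`` declaration, else the global slot definition.

The merge is field-wise: a field left unset at one level inherits its value
from the next. Mixins linearize after the ``is_a`` chain (single-inheritance
backbone; ``is_a`` wins ties).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from .errors import (
    ConflictingIdentifier,
    CycleDetected,
    IntegrityError,
    UnknownClass,
    UnknownSlotReference,
)
from .schema_io import (
    BUILTIN_TYPES,
    SchemaDefinition,
    SlotDefinition,
)

__all__ = [
    "InducedSlot",
    "MaterializedSchema",
    "class_ancestors",
    "induced_slots",
    "materialize",
]

#: SlotDefinition fields subject to field-wise override resolution.
_MERGE_FIELDS = (
    "description",
    "range",
    "required",
    "multivalued",
    "identifier",
    "pattern",
    "slot_uri",
    "unit",
)


@dataclass
class InducedSlot:
    """A slot after inheritance and usage-override resolution.

    ``provenance`` records, for every populated field, which class supplied
    the winning value and from which construct (``attribute``, ``slot``,
    or ``slot_usage``).
    """

    owner: str
    definition: SlotDefinition
    provenance: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def name(self) -> str:
        return self.definition.name

    @property
    def required(self) -> bool:
        return bool(self.definition.required)

    @property
    def multivalued(self) -> bool:
        return bool(self.definition.multivalued)

    @property
    def identifier(self) -> bool:
        return bool(self.definition.identifier)


@dataclass
class MaterializedSchema:
    """A schema plus its compiled ancestry and induced-slot maps."""

    source: SchemaDefinition
    ancestry: dict[str, list[str]]
    induced: dict[str, list[InducedSlot]]
    identifier_slot: dict[str, str | None]

    def effective_range(self, slot: SlotDefinition | InducedSlot) -> str:
        definition = slot.definition if isinstance(slot, InducedSlot) else slot
        return definition.range or self.source.default_range or "string"

    def range_kind(self, range_name: str) -> str:
        """'type', 'enum' or 'class' — which category a range name hits."""
        if range_name in self.source.types or range_name in BUILTIN_TYPES:
            return "type"
        if range_name in self.source.enums:
            return "enum"
        if range_name in self.source.classes:
            return "class"
        raise UnknownSlotReference(f"range {range_name!r} is not declared")

    def range_base(self, range_name: str) -> str:
        """Primitive base of a type range (resolving user types)."""
        t = self.source.types.get(range_name) or BUILTIN_TYPES.get(range_name)
        if t is None:
            raise UnknownSlotReference(f"type {range_name!r} is not declared")
        return t.base


def class_ancestors(schema: SchemaDefinition, class_name: str) -> list[str]:
    """Linearized ancestry, starting with the class itself.

    The ``is_a`` chain comes first, then mixins depth-first left-to-right;
    duplicates are removed keeping the first occurrence (so on a diamond the
    order matches a topological walk that prefers the is_a backbone).
    """
    if class_name not in schema.classes:
        raise UnknownClass(f"class {class_name!r} not in schema")
    order: list[str] = []

    def visit(name: str, path: tuple[str, ...]) -> None:
        if name in path:
            cycle = " -> ".join(path[path.index(name):] + (name,))
            raise CycleDetected(f"inheritance cycle: {cycle}")
        if name not in schema.classes:
            raise UnknownClass(
                f"class {path[-1]!r} inherits from undeclared class {name!r}"
            )
        if name not in order:
            order.append(name)
        cls = schema.classes[name]
        if cls.is_a:
            visit(cls.is_a, path + (name,))
        for mixin in cls.mixins:
            visit(mixin, path + (name,))

    visit(class_name, ())
    return order


def _overlay(base: SlotDefinition, partial: SlotDefinition, source_class: str,
             construct: str, provenance: list[tuple[str, str, str]]) -> None:
    """Apply set fields of a partial slot definition onto *base* in place."""
    for fname in _MERGE_FIELDS:
        value = getattr(partial, fname)
        if value is not None:
            setattr(base, fname, value)
            provenance.append((source_class, fname, construct))
    if partial.mappings:
        base.mappings = list(partial.mappings)
        provenance.append((source_class, "mappings", construct))


def induced_slots(schema: SchemaDefinition, class_name: str) -> list[InducedSlot]:
    """Resolve the effective slots of a class.

    Order: ancestor-inherited slots first (root-most ancestor first), then
    the class's own; within one class, ``slots`` references before
    ``attributes``. Duplicate names keep their first (root-most) position
    while the definition is resolved with nearest-wins precedence.
    """
    ancestry = class_ancestors(schema, class_name)
    root_first = list(reversed(ancestry))

    # collection order: root-most ancestor's slots first, then downward
    slot_order: list[str] = []
    for cname in root_first:
        cls = schema.classes[cname]
        for sname in list(cls.slots) + list(cls.attributes):
            if sname not in slot_order:
                slot_order.append(sname)

    induced: list[InducedSlot] = []
    for sname in slot_order:
        base: SlotDefinition | None = None
        provenance: list[tuple[str, str, str]] = []
        # base definition: global slot if referenced, overridden by the
        # root-most-to-nearest attribute declarations (nearest wins by
        # applying later declarations last)
        referenced = any(
            sname in schema.classes[c].slots for c in root_first
        )
        if referenced:
            if sname not in schema.slots:
                raise UnknownSlotReference(
                    f"class {class_name!r}: slot {sname!r} referenced but "
                    "not defined as a schema-level slot"
                )
            base = copy.deepcopy(schema.slots[sname])
            provenance = [("<schema>", f, "slot") for f in _MERGE_FIELDS
                          if getattr(base, f) is not None]
        for cname in root_first:
            attr = schema.classes[cname].attributes.get(sname)
            if attr is not None:
                if base is None:
                    base = copy.deepcopy(attr)
                    provenance = [(cname, f, "attribute") for f in _MERGE_FIELDS
                                  if getattr(base, f) is not None]
                else:
                    _overlay(base, attr, cname, "attribute", provenance)
        assert base is not None  # slot_order only holds declared names
        # usage overrides, root-most first so nearer classes win
        for cname in root_first:
            usage = schema.classes[cname].slot_usage.get(sname)
            if usage is not None:
                _overlay(base, usage, cname, "slot_usage", provenance)
        if base.identifier:
            base.required = True  # identifiers are implicitly mandatory
        induced.append(InducedSlot(owner=class_name, definition=base,
                                   provenance=provenance))

    identifiers = [s.name for s in induced if s.identifier]
    if len(identifiers) > 1:
        raise ConflictingIdentifier(
            f"class {class_name!r} induces multiple identifier slots: "
            f"{identifiers}"
        )
    return induced


def materialize(schema: SchemaDefinition) -> MaterializedSchema:
    """Compile ancestry + induced slots for every class, checking integrity.

    All dangling references (unknown is_a targets, slot references, ranges)
    are aggregated into a single :class:`IntegrityError` rather than failing
    on the first. Deterministic for equal input, and idempotent on the
    source view. Imports must already be resolved.
    """
    problems: list[str] = []
    ancestry: dict[str, list[str]] = {}
    induced: dict[str, list[InducedSlot]] = {}
    identifier_slot: dict[str, str | None] = {}

    declared = set(schema.types) | set(BUILTIN_TYPES) | set(schema.enums) | set(
        schema.classes
    )

    for cname in schema.classes:
        try:
            ancestry[cname] = class_ancestors(schema, cname)
        except (UnknownClass, CycleDetected) as exc:
            problems.append(str(exc))
            continue
        try:
            slots = induced_slots(schema, cname)
        except (UnknownSlotReference, ConflictingIdentifier) as exc:
            problems.append(str(exc))
            continue
        induced[cname] = slots
        ids = [s.name for s in slots if s.identifier]
        identifier_slot[cname] = ids[0] if ids else None
        for slot in slots:
            rng = slot.definition.range or schema.default_range or "string"
            if rng not in declared:
                problems.append(
                    f"class {cname!r} slot {slot.name!r}: range {rng!r} "
                    "names no declared type, class, or enum"
                )

    if problems:
        raise IntegrityError(problems)
    return MaterializedSchema(
        source=schema,
        ancestry=ancestry,
        induced=induced,
        identifier_slot=identifier_slot,
    )
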