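"""Declarative schema and data transformations.

Schemas evolve: a project renames a field to match a partner's
terminology, splits a fused ``position`` cell into ``latitude`` and
``longitude``, subsets a large community model down to what it needs. This
module expresses such changes as an ordered list of declarative
operations — rename, split, merge, retype, recardinalize, subset — that
apply coherently to *both* the schema (deriving the target schema) and the
instance data (migrating documents), with an audit trail.

The YAML grammar is a list of operation mappings, e.g.::

    - op: split
      class: Sample
      slot: position
      targets: [latitude, longitude]
      delimiter: ","
      target_ranges: [float, float]
    - op: rename
      class: Sample
      from: environment_type
      to: sample_type

Split uses exact arity: the source string must divide on the delimiter
into exactly ``len(targets)`` parts (trimmed, cast to the target ranges);
anything else is reported as an error with the document path. A missing
source value propagates absence to every target.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Optional, Union

import yaml

from .compiler import MaterializedSchema
from .errors import (
    CastError,
    SplitArityMismatch,
    TransformError,
    TransformReferenceError,
    UnknownOperationKind,
)
from .schema_io import SchemaDefinition, SlotDefinition
from .validator import InstanceDocument

__all__ = [
    "TransformSpec",
    "TransformResult",
    "Rename",
    "Split",
    "Merge",
    "Retype",
    "Recardinalize",
    "Subset",
    "parse_transform_spec",
    "derive_schema",
    "transform_instance",
]


@dataclass
class Rename:
    class_name: str
    old_slot: str
    new_slot: str


@dataclass
class Split:
    class_name: str
    source_slot: str
    targets: list[str]
    delimiter: str = ","
    target_ranges: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.targets) < 2:
            raise TransformError("split needs at least 2 target slots")
        if self.target_ranges and len(self.target_ranges) != len(self.targets):
            raise TransformError(
                "split target_ranges length must match targets length"
            )


@dataclass
class Merge:
    class_name: str
    sources: list[str]
    target_slot: str
    delimiter: str = ","


@dataclass
class Retype:
    class_name: str
    slot: str
    new_range: str


@dataclass
class Recardinalize:
    class_name: str
    slot: str
    required: Optional[bool] = None
    multivalued: Optional[bool] = None


@dataclass
class Subset:
    keep_classes: list[str]
    keep_slots: dict[str, list[str]] = field(default_factory=dict)


Operation = Union[Rename, Split, Merge, Retype, Recardinalize, Subset]


@dataclass
class TransformSpec:
    operations: list[Operation] = field(default_factory=list)


@dataclass
class TransformResult:
    derived_schema: SchemaDefinition
    audit: list[dict] = field(default_factory=list)


_OP_FIELDS = {
    "rename": {"class", "from", "to"},
    "split": {"class", "slot", "targets", "delimiter", "target_ranges"},
    "merge": {"class", "sources", "target", "delimiter"},
    "retype": {"class", "slot", "range"},
    "recardinalize": {"class", "slot", "required", "multivalued"},
    "subset": {"keep_classes", "keep_slots"},
}


def _require(block: dict, key: str, kind: str):
    if key not in block:
        raise TransformError(f"{kind} operation missing required field {key!r}")
    return block[key]


def parse_transform_spec(text: str) -> TransformSpec:
    """Parse a YAML operation list into a validated :class:`TransformSpec`."""
    doc = yaml.safe_load(text)
    if doc is None:
        return TransformSpec()
    if not isinstance(doc, list):
        raise TransformError("transform spec must be a YAML list of operations")
    ops: list[Operation] = []
    for i, block in enumerate(doc):
        if not isinstance(block, dict) or "op" not in block:
            raise TransformError(f"operation #{i}: missing 'op' field")
        kind = block["op"]
        if kind not in _OP_FIELDS:
            raise UnknownOperationKind(
                f"operation #{i}: unknown kind {kind!r}; known: "
                f"{sorted(_OP_FIELDS)}"
            )
        extra = set(block) - _OP_FIELDS[kind] - {"op"}
        if extra:
            raise TransformError(
                f"operation #{i} ({kind}): unknown fields {sorted(extra)}"
            )
        if kind == "rename":
            ops.append(
                Rename(
                    class_name=_require(block, "class", kind),
                    old_slot=_require(block, "from", kind),
                    new_slot=_require(block, "to", kind),
                )
            )
        elif kind == "split":
            ops.append(
                Split(
                    class_name=_require(block, "class", kind),
                    source_slot=_require(block, "slot", kind),
                    targets=list(_require(block, "targets", kind)),
                    delimiter=str(block.get("delimiter", ",")),
                    target_ranges=list(block.get("target_ranges", [])),
                )
            )
        elif kind == "merge":
            ops.append(
                Merge(
                    class_name=_require(block, "class", kind),
                    sources=list(_require(block, "sources", kind)),
                    target_slot=_require(block, "target", kind),
                    delimiter=str(block.get("delimiter", ",")),
                )
            )
        elif kind == "retype":
            ops.append(
                Retype(
                    class_name=_require(block, "class", kind),
                    slot=_require(block, "slot", kind),
                    new_range=_require(block, "range", kind),
                )
            )
        elif kind == "recardinalize":
            ops.append(
                Recardinalize(
                    class_name=_require(block, "class", kind),
                    slot=_require(block, "slot", kind),
                    required=block.get("required"),
                    multivalued=block.get("multivalued"),
                )
            )
        else:  # subset
            ops.append(
                Subset(
                    keep_classes=list(_require(block, "keep_classes", kind)),
                    keep_slots={
                        k: list(v)
                        for k, v in (block.get("keep_slots") or {}).items()
                    },
                )
            )
    return TransformSpec(operations=ops)


def _find_slot(schema: SchemaDefinition, class_name: str, slot_name: str,
               op_index: int) -> SlotDefinition:
    cls = schema.classes.get(class_name)
    if cls is None:
        raise TransformReferenceError(op_index, class_name)
    if slot_name in cls.attributes:
        return cls.attributes[slot_name]
    if slot_name in cls.slots and slot_name in schema.slots:
        # pull the shared definition down so the edit stays class-local
        pulled = copy.deepcopy(schema.slots[slot_name])
        cls.slots.remove(slot_name)
        cls.attributes[slot_name] = pulled
        return pulled
    raise TransformReferenceError(op_index, f"{class_name}.{slot_name}")


def derive_schema(
    schema: SchemaDefinition, spec: TransformSpec
) -> TransformResult:
    """Apply the spec's operations, in order, to a copy of *schema*.

    Split removes the source slot and appends the targets with the given
    ranges; rename preserves every other slot field; subset drops unlisted
    classes (and slots, when ``keep_slots`` names them) with an audit
    record. Dangling references raise :class:`TransformReferenceError`
    naming the operation index.
    """
    derived = copy.deepcopy(schema)
    audit: list[dict] = []
    for i, op in enumerate(spec.operations):
        if isinstance(op, Rename):
            slot = _find_slot(derived, op.class_name, op.old_slot, i)
            cls = derived.classes[op.class_name]
            slot.name = op.new_slot
            cls.attributes = {
                (op.new_slot if k == op.old_slot else k): v
                for k, v in cls.attributes.items()
            }
            audit.append({"op": "rename", "class": op.class_name,
                          "from": op.old_slot, "to": op.new_slot})
        elif isinstance(op, Split):
            source = _find_slot(derived, op.class_name, op.source_slot, i)
            cls = derived.classes[op.class_name]
            del cls.attributes[op.source_slot]
            ranges = op.target_ranges or ["string"] * len(op.targets)
            for target, rng in zip(op.targets, ranges):
                cls.attributes[target] = SlotDefinition(
                    name=target,
                    description=source.description,
                    range=rng,
                    required=source.required,
                )
            audit.append({"op": "split", "class": op.class_name,
                          "from": op.source_slot, "to": list(op.targets)})
        elif isinstance(op, Merge):
            cls = derived.classes.get(op.class_name)
            if cls is None:
                raise TransformReferenceError(i, op.class_name)
            sources = [_find_slot(derived, op.class_name, s, i)
                       for s in op.sources]
            required = all(bool(s.required) for s in sources)
            for s in op.sources:
                del derived.classes[op.class_name].attributes[s]
            derived.classes[op.class_name].attributes[op.target_slot] = (
                SlotDefinition(
                    name=op.target_slot,
                    description=sources[0].description,
                    range="string",
                    required=required or None,
                )
            )
            audit.append({"op": "merge", "class": op.class_name,
                          "from": list(op.sources), "to": op.target_slot})
        elif isinstance(op, Retype):
            slot = _find_slot(derived, op.class_name, op.slot, i)
            old = slot.range
            slot.range = op.new_range
            audit.append({"op": "retype", "class": op.class_name,
                          "slot": op.slot, "from": old, "to": op.new_range})
        elif isinstance(op, Recardinalize):
            slot = _find_slot(derived, op.class_name, op.slot, i)
            if op.required is not None:
                slot.required = op.required
            if op.multivalued is not None:
                slot.multivalued = op.multivalued
            audit.append({"op": "recardinalize", "class": op.class_name,
                          "slot": op.slot, "required": op.required,
                          "multivalued": op.multivalued})
        elif isinstance(op, Subset):
            missing = [c for c in op.keep_classes if c not in derived.classes]
            if missing:
                raise TransformReferenceError(i, ", ".join(missing))
            dropped = [c for c in derived.classes if c not in op.keep_classes]
            for cname in dropped:
                del derived.classes[cname]
            # prune slots whose class range was dropped
            pruned: list[str] = []
            for cname, cls in derived.classes.items():
                keep = op.keep_slots.get(cname)
                for sname in list(cls.attributes):
                    slot = cls.attributes[sname]
                    if (keep is not None and sname not in keep) or (
                        slot.range in dropped
                    ):
                        del cls.attributes[sname]
                        pruned.append(f"{cname}.{sname}")
                cls.slots = [
                    s for s in cls.slots
                    if keep is None or s in keep
                ]
                if cls.is_a in dropped:
                    cls.is_a = None
                cls.mixins = [m for m in cls.mixins if m not in dropped]
            audit.append({"op": "subset", "kept": list(op.keep_classes),
                          "dropped_classes": dropped,
                          "dropped_slots": pruned})
    return TransformResult(derived_schema=derived, audit=audit)


def _cast(text: str, range_name: str, path: str,
          source: Optional[MaterializedSchema]) -> Any:
    base = range_name
    if source is not None:
        try:
            if source.range_kind(range_name) == "type":
                base = source.range_base(range_name)
            else:
                base = "string"
        except Exception:
            base = range_name
    try:
        if base == "integer":
            return int(text)
        if base == "float":
            return float(text)
        if base == "boolean":
            if text.lower() in ("true", "false"):
                return text.lower() == "true"
            raise ValueError(text)
    except ValueError as exc:
        raise CastError(path, text, range_name) from exc
    return text


def transform_instance(
    doc: InstanceDocument,
    spec: TransformSpec,
    source: Optional[MaterializedSchema] = None,
) -> InstanceDocument:
    """Migrate one document along the spec's operations, in order.

    Values of untouched slots pass through unchanged. *source* (the
    materialized source schema) is used to resolve target ranges of casts;
    without it, split targets are cast by the literal range name
    (integer/float/boolean, else kept as text).
    """
    values: dict[str, Any] = copy.deepcopy(doc.values)
    class_name = doc.class_name
    for op in spec.operations:
        if isinstance(op, Rename):
            if op.class_name != class_name:
                continue
            if op.old_slot in values:
                values = {
                    (op.new_slot if k == op.old_slot else k): v
                    for k, v in values.items()
                }
        elif isinstance(op, Split):
            if op.class_name != class_name:
                continue
            raw = values.pop(op.source_slot, None)
            if raw is None or (isinstance(raw, str) and raw.strip() == ""):
                continue  # absence propagates: all targets stay absent
            parts = [p.strip() for p in str(raw).split(op.delimiter)]
            if len(parts) != len(op.targets):
                raise SplitArityMismatch(
                    f"/{op.source_slot}", len(parts), len(op.targets)
                )
            ranges = op.target_ranges or ["string"] * len(op.targets)
            for target, rng, part in zip(op.targets, ranges, parts):
                values[target] = _cast(part, rng, f"/{target}", source)
        elif isinstance(op, Merge):
            if op.class_name != class_name:
                continue
            present = [s for s in op.sources if s in values]
            if not present:
                continue
            parts = [str(values.pop(s)) for s in present]
            values[op.target_slot] = op.delimiter.join(parts)
        elif isinstance(op, Recardinalize):
            if op.class_name != class_name or op.slot not in values:
                continue
            value = values[op.slot]
            if op.multivalued is True and not isinstance(value, list):
                values[op.slot] = [value]
            elif op.multivalued is False and isinstance(value, list):
                values[op.slot] = value[0] if value else None
        elif isinstance(op, Subset):
            keep = op.keep_slots.get(class_name)
            if keep is not None:
                values = {k: v for k, v in values.items() if k in keep}
        # Retype: schema-level only; data passes through (the validator of
        # the derived schema will flag values that no longer conform)
    return InstanceDocument(class_name=class_name, values=values)
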