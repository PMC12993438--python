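"""Schema definitions: in-memory model, YAML parsing/emission, imports.

A schema is authored as a YAML mapping whose top level carries metadata
(``id`` — a URI, mandatory — plus ``name``, ``title``, ``license``), a
``prefixes`` block, an ``imports`` list, and the four element maps:
``types``, ``enums``, ``slots`` and ``classes``.

Three-state booleans: slot flags (``required``, ``multivalued``,
``identifier``) are ``None`` when the author did not state them. The
distinction matters for inheritance — an unset field defers to the parent
definition — and for faithful round-tripping; effective defaults (false)
are applied during compilation, not parsing.

Unknown keys are never dropped silently: they are preserved in a per-element
``annotations`` side-map, re-emitted on output, and recorded in the schema's
``warnings`` list.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import yaml

from .errors import (
    DuplicateElementName,
    ImportCycle,
    MissingSchemaId,
    PrefixConflict,
    SchemaParseError,
    UnresolvableImport,
)
from .metamodel import Mapping, PrefixMap, is_uri

__all__ = [
    "SchemaDefinition",
    "ClassDefinition",
    "SlotDefinition",
    "EnumDefinition",
    "TypeDefinition",
    "PermissibleValue",
    "BUILTIN_TYPES",
    "PRIMITIVE_BASES",
    "parse_schema",
    "emit_schema",
    "resolve_imports",
]

PRIMITIVE_BASES = (
    "string",
    "integer",
    "float",
    "boolean",
    "uri",
    "uriorcurie",
    "date",
    "datetime",
)

_MAPPING_KEYS = {
    "exact_mappings": "exact",
    "close_mappings": "close",
    "broad_mappings": "broad",
    "narrow_mappings": "narrow",
    "related_mappings": "related",
}


@dataclass
class SlotDefinition:
    """A named attribute: range, cardinality flags, metadata.

    Also used (with most fields ``None``) as the *partial* definition inside
    a class's ``slot_usage`` block.
    """

    name: str
    description: Optional[str] = None
    range: Optional[str] = None
    required: Optional[bool] = None
    multivalued: Optional[bool] = None
    identifier: Optional[bool] = None
    pattern: Optional[str] = None
    slot_uri: Optional[str] = None
    unit: Optional[str] = None
    mappings: list[Mapping] = field(default_factory=list)
    annotations: dict = field(default_factory=dict)


@dataclass
class ClassDefinition:
    name: str
    description: Optional[str] = None
    is_a: Optional[str] = None
    mixins: list[str] = field(default_factory=list)
    abstract: bool = False
    slots: list[str] = field(default_factory=list)
    attributes: dict[str, SlotDefinition] = field(default_factory=dict)
    slot_usage: dict[str, SlotDefinition] = field(default_factory=dict)
    class_uri: Optional[str] = None
    mappings: list[Mapping] = field(default_factory=list)
    annotations: dict = field(default_factory=dict)


@dataclass
class PermissibleValue:
    text: str
    description: Optional[str] = None
    meaning: Optional[str] = None


@dataclass
class EnumDefinition:
    """Controlled vocabulary; values optionally carry an ontology ``meaning``."""

    name: str
    description: Optional[str] = None
    permissible_values: dict[str, PermissibleValue] = field(default_factory=dict)
    case_insensitive: bool = False
    annotations: dict = field(default_factory=dict)


@dataclass
class TypeDefinition:
    name: str
    base: str = "string"
    uri: Optional[str] = None
    pattern: Optional[str] = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.base not in PRIMITIVE_BASES:
            raise SchemaParseError(
                f"type {self.name!r}: base {self.base!r} is not one of "
                f"{PRIMITIVE_BASES}"
            )


#: Implicitly available primitive types; schemas use them without declaring
#: them, the way a standard type library would be imported.
BUILTIN_TYPES: dict[str, TypeDefinition] = {
    name: TypeDefinition(name=name, base=name, uri=f"xsd:{xsd}")
    for name, xsd in [
        ("string", "string"),
        ("integer", "integer"),
        ("float", "float"),
        ("boolean", "boolean"),
        ("uri", "anyURI"),
        ("uriorcurie", "anyURI"),
        ("date", "date"),
        ("datetime", "dateTime"),
    ]
}


@dataclass
class SchemaDefinition:
    """The parsed schema container."""

    id: str
    name: str
    title: Optional[str] = None
    license: Optional[str] = None
    prefixes: PrefixMap = field(default_factory=PrefixMap)
    imports: list[str] = field(default_factory=list)
    default_range: Optional[str] = None
    classes: dict[str, ClassDefinition] = field(default_factory=dict)
    slots: dict[str, SlotDefinition] = field(default_factory=dict)
    enums: dict[str, EnumDefinition] = field(default_factory=dict)
    types: dict[str, TypeDefinition] = field(default_factory=dict)
    annotations: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list, compare=False)

    def element_names(self) -> dict[str, list[str]]:
        return {
            "class": list(self.classes),
            "slot": list(self.slots),
            "enum": list(self.enums),
            "type": list(self.types),
        }


# --- YAML loading -------------------------------------------------------------

class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys with line info."""


def _construct_mapping(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise DuplicateElementName(
                f"duplicate key {key!r} at line {key_node.start_mark.line + 1}"
            )
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _construct_mapping
)


def _pop_mappings(block: dict) -> list[Mapping]:
    out = []
    for key, predicate in _MAPPING_KEYS.items():
        for target in block.pop(key, []) or []:
            out.append(Mapping(predicate=predicate, target=str(target)))
    return out


def _parse_slot(name: str, block, warnings: list[str], context: str) -> SlotDefinition:
    if block is None:
        block = {}
    if not isinstance(block, dict):
        raise SchemaParseError(f"{context}: slot {name!r} body must be a mapping")
    block = dict(block)
    slot = SlotDefinition(
        name=name,
        description=block.pop("description", None),
        range=block.pop("range", None),
        required=block.pop("required", None),
        multivalued=block.pop("multivalued", None),
        identifier=block.pop("identifier", None),
        pattern=block.pop("pattern", None),
        slot_uri=block.pop("slot_uri", None),
        unit=block.pop("unit", None),
        mappings=_pop_mappings(block),
    )
    if block:
        slot.annotations = block
        warnings.append(f"{context}: slot {name!r}: unrecognized keys {sorted(block)}")
    return slot


def _parse_class(name: str, block, warnings: list[str]) -> ClassDefinition:
    if block is None:
        block = {}
    block = dict(block)
    attributes = {
        attr_name: _parse_slot(attr_name, attr_block, warnings, f"class {name}")
        for attr_name, attr_block in (block.pop("attributes", None) or {}).items()
    }
    slot_usage = {
        s_name: _parse_slot(s_name, s_block, warnings, f"class {name} slot_usage")
        for s_name, s_block in (block.pop("slot_usage", None) or {}).items()
    }
    cls = ClassDefinition(
        name=name,
        description=block.pop("description", None),
        is_a=block.pop("is_a", None),
        mixins=list(block.pop("mixins", None) or []),
        abstract=bool(block.pop("abstract", False)),
        slots=list(block.pop("slots", None) or []),
        attributes=attributes,
        slot_usage=slot_usage,
        class_uri=block.pop("class_uri", None),
        mappings=_pop_mappings(block),
    )
    if block:
        cls.annotations = block
        warnings.append(f"class {name!r}: unrecognized keys {sorted(block)}")
    return cls


def _parse_enum(name: str, block, warnings: list[str]) -> EnumDefinition:
    block = dict(block or {})
    pvs: dict[str, PermissibleValue] = {}
    for text, pv_block in (block.pop("permissible_values", None) or {}).items():
        pv_block = dict(pv_block or {})
        pvs[str(text)] = PermissibleValue(
            text=str(text),
            description=pv_block.pop("description", None),
            meaning=pv_block.pop("meaning", None),
        )
        if pv_block:
            warnings.append(
                f"enum {name!r} value {text!r}: unrecognized keys {sorted(pv_block)}"
            )
    enum = EnumDefinition(
        name=name,
        description=block.pop("description", None),
        permissible_values=pvs,
        case_insensitive=bool(block.pop("case_insensitive", False)),
    )
    if block:
        enum.annotations = block
        warnings.append(f"enum {name!r}: unrecognized keys {sorted(block)}")
    return enum


def _parse_type(name: str, block, warnings: list[str]) -> TypeDefinition:
    block = dict(block or {})
    t = TypeDefinition(
        name=name,
        base=block.pop("base", "string"),
        uri=block.pop("uri", None),
        pattern=block.pop("pattern", None),
    )
    if block:
        t.annotations = block
        warnings.append(f"type {name!r}: unrecognized keys {sorted(block)}")
    return t


def parse_schema(text: str) -> SchemaDefinition:
    """Parse a YAML schema document into a :class:`SchemaDefinition`.

    Raises :class:`MissingSchemaId` when ``id`` is absent or not a URI,
    :class:`DuplicateElementName` on duplicate keys (YAML would otherwise
    keep only the last), and lets YAML syntax errors propagate with their
    line information.
    """
    doc = yaml.load(text, Loader=_StrictLoader)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise SchemaParseError("schema document root must be a mapping")
    doc = dict(doc)
    schema_id = doc.pop("id", None)
    if not schema_id or not is_uri(str(schema_id)):
        raise MissingSchemaId(
            f"schema must declare a URI 'id'; got {schema_id!r}"
        )
    warnings: list[str] = []
    schema = SchemaDefinition(
        id=str(schema_id),
        name=str(doc.pop("name", "") or ""),
        title=doc.pop("title", None),
        license=doc.pop("license", None),
        prefixes=PrefixMap(
            {str(p): str(b) for p, b in (doc.pop("prefixes", None) or {}).items()}
        ),
        imports=list(doc.pop("imports", None) or []),
        default_range=doc.pop("default_range", None),
    )
    schema.types = {
        n: _parse_type(n, b, warnings) for n, b in (doc.pop("types", None) or {}).items()
    }
    schema.enums = {
        n: _parse_enum(n, b, warnings) for n, b in (doc.pop("enums", None) or {}).items()
    }
    schema.slots = {
        n: _parse_slot(n, b, warnings, "schema") for n, b in (doc.pop("slots", None) or {}).items()
    }
    schema.classes = {
        n: _parse_class(n, b, warnings) for n, b in (doc.pop("classes", None) or {}).items()
    }
    if doc:
        schema.annotations = doc
        warnings.append(f"schema: unrecognized top-level keys {sorted(doc)}")
    schema.warnings = warnings
    return schema


# --- YAML emission ------------------------------------------------------------

def _emit_mappings(mappings: list[Mapping]) -> dict:
    out: dict[str, list[str]] = {}
    for key, predicate in _MAPPING_KEYS.items():
        targets = [m.target for m in mappings if m.predicate == predicate]
        if targets:
            out[key] = targets
    return out


def _slot_block(slot: SlotDefinition) -> dict:
    block: dict = {}
    if slot.description is not None:
        block["description"] = slot.description
    if slot.range is not None:
        block["range"] = slot.range
    for flag in ("required", "multivalued", "identifier"):
        value = getattr(slot, flag)
        if value is not None:
            block[flag] = value
    if slot.pattern is not None:
        block["pattern"] = slot.pattern
    if slot.slot_uri is not None:
        block["slot_uri"] = slot.slot_uri
    if slot.unit is not None:
        block["unit"] = slot.unit
    block.update(_emit_mappings(slot.mappings))
    block.update(slot.annotations)
    return block


def _class_block(cls: ClassDefinition) -> dict:
    block: dict = {}
    if cls.description is not None:
        block["description"] = cls.description
    if cls.is_a is not None:
        block["is_a"] = cls.is_a
    if cls.mixins:
        block["mixins"] = list(cls.mixins)
    if cls.abstract:
        block["abstract"] = True
    if cls.class_uri is not None:
        block["class_uri"] = cls.class_uri
    if cls.slots:
        block["slots"] = list(cls.slots)
    if cls.attributes:
        block["attributes"] = {n: _slot_block(s) for n, s in cls.attributes.items()}
    if cls.slot_usage:
        block["slot_usage"] = {n: _slot_block(s) for n, s in cls.slot_usage.items()}
    block.update(_emit_mappings(cls.mappings))
    block.update(cls.annotations)
    return block


def _enum_block(enum: EnumDefinition) -> dict:
    block: dict = {}
    if enum.description is not None:
        block["description"] = enum.description
    if enum.case_insensitive:
        block["case_insensitive"] = True
    pvs: dict = {}
    for text, pv in enum.permissible_values.items():
        pv_block: dict = {}
        if pv.description is not None:
            pv_block["description"] = pv.description
        if pv.meaning is not None:
            pv_block["meaning"] = pv.meaning
        pvs[text] = pv_block
    block["permissible_values"] = pvs
    block.update(enum.annotations)
    return block


def _type_block(t: TypeDefinition) -> dict:
    block: dict = {"base": t.base}
    if t.uri is not None:
        block["uri"] = t.uri
    if t.pattern is not None:
        block["pattern"] = t.pattern
    block.update(t.annotations)
    return block


class _Dumper(yaml.SafeDumper):
    pass


_Dumper.add_representer(
    dict,
    lambda dumper, data: dumper.represent_mapping(
        yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, data.items()
    ),
)


def emit_schema(schema: SchemaDefinition) -> str:
    """Serialize to YAML with a fixed key order.

    Deterministic: metadata, prefixes, imports, default_range, then types,
    enums, slots, classes in definition order. ``parse_schema`` of the
    output is structurally equal to the input.
    """
    doc: dict = {"id": schema.id, "name": schema.name}
    if schema.title is not None:
        doc["title"] = schema.title
    if schema.license is not None:
        doc["license"] = schema.license
    if len(schema.prefixes):
        doc["prefixes"] = schema.prefixes.as_dict()
    if schema.imports:
        doc["imports"] = list(schema.imports)
    if schema.default_range is not None:
        doc["default_range"] = schema.default_range
    if schema.types:
        doc["types"] = {n: _type_block(t) for n, t in schema.types.items()}
    if schema.enums:
        doc["enums"] = {n: _enum_block(e) for n, e in schema.enums.items()}
    if schema.slots:
        doc["slots"] = {n: _slot_block(s) for n, s in schema.slots.items()}
    if schema.classes:
        doc["classes"] = {n: _class_block(c) for n, c in schema.classes.items()}
    doc.update(schema.annotations)
    return yaml.dump(
        doc,
        Dumper=_Dumper,
        sort_keys=False,
        default_flow_style=False,
        allow_unicode=True,
    )


# --- import resolution --------------------------------------------------------

Resolver = Union[Callable[[str], str], dict[str, str]]


def _resolve_one(name: str, resolver: Resolver) -> str:
    try:
        if isinstance(resolver, dict):
            return resolver[name]
        return resolver(name)
    except KeyError as exc:
        raise UnresolvableImport(f"cannot resolve import {name!r}") from exc


def _merge(target: SchemaDefinition, imported: SchemaDefinition) -> None:
    """Merge *imported* into *target*; target's definitions shadow."""
    for prefix, base in imported.prefixes.items():
        if prefix in target.prefixes:
            if target.prefixes[prefix] != base:
                raise PrefixConflict(
                    f"prefix {prefix!r} bound to {target.prefixes[prefix]!r} "
                    f"and {base!r}"
                )
        else:
            target.prefixes.bind(prefix, base)
    for category in ("classes", "slots", "enums", "types"):
        own = getattr(target, category)
        theirs = getattr(imported, category)
        for name, element in theirs.items():
            if name in own:
                target.warnings.append(
                    f"import {imported.name!r}: local {category[:-2]}"
                    f" definition {name!r} shadows imported one"
                )
            else:
                own[name] = copy.deepcopy(element)


def resolve_imports(schema: SchemaDefinition, resolver: Resolver) -> SchemaDefinition:
    """Compute the import closure and merge it into a new schema.

    Depth-first over the ``imports`` lists; the importing schema's
    definitions win name collisions (recorded as warnings). Conflicting
    prefix bindings raise :class:`PrefixConflict`; cyclic imports raise
    :class:`ImportCycle`. Resolution is idempotent.
    """
    merged = copy.deepcopy(schema)

    in_progress: list[str] = ["<root>"]
    loaded: dict[str, SchemaDefinition] = {}

    def load(name: str) -> SchemaDefinition:
        if name in in_progress:
            chain = " -> ".join(in_progress[1:] + [name])
            raise ImportCycle(f"import cycle: {chain}")
        if name in loaded:
            return loaded[name]
        in_progress.append(name)
        sub = parse_schema(_resolve_one(name, resolver))
        for sub_import in sub.imports:
            _merge(sub, load(sub_import))
        in_progress.pop()
        loaded[name] = sub
        return sub

    for name in schema.imports:
        _merge(merged, load(name))
    return merged
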