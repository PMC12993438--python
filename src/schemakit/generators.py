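"""Derive downstream artifacts from a materialized schema.

Three generators: JSON Schema (draft 2020-12, pinned), Markdown
documentation with a class-relationship edge list, and minimal SQL DDL.
Each artifact is deterministic for equal input and ships a machine-readable
*loss report* enumerating schema features the target formalism cannot
express (e.g. identifier uniqueness in JSON Schema) — conversions are
constrained by the expressiveness of the target and such losses should be
visible, not silent.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .compiler import InducedSlot, MaterializedSchema
from .errors import UnknownClass

__all__ = [
    "GeneratedArtifact",
    "gen_json_schema",
    "gen_markdown_docs",
    "gen_sql_ddl",
    "snake_case",
]

JSON_SCHEMA_DIALECT = "https://json-schema.org/draft/2020-12/schema"

# mirrors the native validator's URI / CURIE syntax checks
_URI_PATTERN = r"(://)|^urn:"
_URIORCURIE_PATTERN = r"(://)|^urn:|^[A-Za-z][A-Za-z0-9_.\-]*:\S*$"


@dataclass
class GeneratedArtifact:
    kind: str
    files: dict[str, str] = field(default_factory=dict)

    def write_to(self, directory) -> list[str]:
        from pathlib import Path

        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, content in self.files.items():
            (out / name).write_text(content)
            written.append(str(out / name))
        return written


def _loss_json(kind: str, losses: list[dict], extra: dict | None = None) -> str:
    doc = {"kind": kind, "losses": losses}
    if extra:
        doc.update(extra)
    return json.dumps(doc, indent=2) + "\n"


# --- JSON Schema --------------------------------------------------------------

def _anchored(pattern: str) -> str:
    return f"^(?:{pattern})$"


def _scalar_schema(ms: MaterializedSchema, slot: InducedSlot, rng: str,
                   losses: list[dict]) -> dict:
    base = ms.range_base(rng)
    out: dict
    if base == "integer":
        out = {"type": "integer"}
    elif base == "float":
        out = {"type": "number"}
    elif base == "boolean":
        out = {"type": "boolean"}
    elif base == "uri":
        out = {"type": "string", "pattern": _URI_PATTERN}
    elif base == "uriorcurie":
        out = {"type": "string", "pattern": _URIORCURIE_PATTERN}
    elif base in ("date", "datetime"):
        out = {"type": "string",
               "format": "date" if base == "date" else "date-time"}
        losses.append({
            "code": "format_annotation_only",
            "element": slot.name,
            "detail": f"{base} conformance is a non-asserting format "
                      "annotation in JSON Schema",
        })
    else:
        out = {"type": "string"}
    patterns = []
    user_type = ms.source.types.get(rng)
    if user_type is not None and user_type.pattern:
        patterns.append(user_type.pattern)
    if slot.definition.pattern:
        patterns.append(slot.definition.pattern)
    if patterns:
        if len(patterns) == 1:
            out["pattern"] = _anchored(patterns[0])
        else:
            out["allOf"] = [{"pattern": _anchored(p)} for p in patterns]
    return out


def _slot_schema(ms: MaterializedSchema, slot: InducedSlot,
                 losses: list[dict]) -> dict:
    rng = ms.effective_range(slot)
    kind = ms.range_kind(rng)
    if kind == "class":
        inner: dict = {"$ref": f"#/$defs/{rng}"}
    elif kind == "enum":
        enum = ms.source.enums[rng]
        inner = {"enum": list(enum.permissible_values)}
        if enum.case_insensitive:
            losses.append({
                "code": "case_insensitive_enum",
                "element": rng,
                "detail": "JSON Schema enum matching is case-sensitive",
            })
    else:
        inner = _scalar_schema(ms, slot, rng, losses)
    if slot.multivalued:
        return {"type": "array", "items": inner}
    return inner


def _class_def(ms: MaterializedSchema, class_name: str, losses: list[dict],
               open_world: bool) -> dict:
    properties: dict = {}
    required: list[str] = []
    for slot in ms.induced[class_name]:
        prop = _slot_schema(ms, slot, losses)
        if slot.required:
            required.append(slot.name)
            # native policy: empty string counts as absent
            if prop.get("type") == "string" and "pattern" not in prop \
                    and "enum" not in prop:
                prop["minLength"] = 1
        properties[slot.name] = prop
    out: dict = {
        "type": "object",
        "properties": properties,
        "additionalProperties": bool(open_world),
    }
    cls = ms.source.classes[class_name]
    if cls.description:
        out["description"] = cls.description
    if required:
        out["required"] = required
    return out


def gen_json_schema(ms: MaterializedSchema, root_class: str,
                    open_world: bool = False) -> GeneratedArtifact:
    """One JSON Schema document (draft 2020-12) rooted at *root_class*.

    Every class becomes an object definition under ``$defs`` built from its
    induced slots; class-ranged slots become internal references, enums an
    enumerated string set. ``additionalProperties`` mirrors the
    closed/open-world flag.
    """
    if root_class not in ms.source.classes:
        raise UnknownClass(root_class)
    losses: list[dict] = []
    defs = {
        name: _class_def(ms, name, losses, open_world)
        for name in ms.source.classes
    }
    for cname, id_slot in ms.identifier_slot.items():
        if id_slot is not None:
            losses.append({
                "code": "identifier_uniqueness",
                "element": cname,
                "detail": f"uniqueness of identifier slot {id_slot!r} across "
                          "a collection is not expressible in JSON Schema",
            })
    doc = {
        "$schema": JSON_SCHEMA_DIALECT,
        "$id": f"{ms.source.id.rstrip('/')}/{root_class}.schema.json",
        "title": root_class,
        "$ref": f"#/$defs/{root_class}",
        "$defs": defs,
    }
    stem = f"{root_class}"
    return GeneratedArtifact(
        kind="json_schema",
        files={
            f"{stem}.schema.json": json.dumps(doc, indent=2) + "\n",
            f"{stem}.schema.loss.json": _loss_json("json_schema", losses),
        },
    )


# --- Markdown documentation ---------------------------------------------------

def _cardinality_token(slot: InducedSlot) -> str:
    if slot.multivalued:
        return "1..*" if slot.required else "0..*"
    return "1" if slot.required else "0..1"


def _slot_pages(ms: MaterializedSchema) -> dict[str, str]:
    """One page per unique slot name (schema-level slots and attributes)."""
    pages: dict[str, str] = {}
    # schema-level slots first, then attributes in class order
    seen: dict[str, tuple[str, object]] = {}
    for name, slot in ms.source.slots.items():
        seen.setdefault(name, ("schema slot", slot))
    for cname, cls in ms.source.classes.items():
        for name, slot in cls.attributes.items():
            seen.setdefault(name, (f"attribute of {cname}", slot))
    for name, (origin, slot) in seen.items():
        lines = [f"# Slot: {name}", ""]
        if slot.description:
            lines += [slot.description, ""]
        lines.append(f"* origin: {origin}")
        lines.append(f"* range: {slot.range or ms.source.default_range or 'string'}")
        for flag in ("required", "multivalued", "identifier"):
            value = getattr(slot, flag)
            if value is not None:
                lines.append(f"* {flag}: {str(bool(value)).lower()}")
        if slot.pattern:
            lines.append(f"* pattern: `{slot.pattern}`")
        if slot.slot_uri:
            lines.append(f"* uri: {slot.slot_uri}")
        if slot.unit:
            lines.append(f"* unit: {slot.unit}")
        for m in slot.mappings:
            lines.append(f"* {m.predicate} mapping: {m.target}")
        pages[f"{name}.md"] = "\n".join(lines) + "\n"
    return pages


def _class_page(ms: MaterializedSchema, cname: str) -> str:
    cls = ms.source.classes[cname]
    lines = [f"# Class: {cname}", ""]
    if cls.description:
        lines += [cls.description, ""]
    if cls.abstract:
        lines.append("*Abstract class.*")
    ancestry = ms.ancestry[cname]
    if len(ancestry) > 1:
        lines.append(f"* inheritance: {' -> '.join(ancestry)}")
    if cls.class_uri:
        lines.append(f"* uri: {cls.class_uri}")
    for m in cls.mappings:
        lines.append(f"* {m.predicate} mapping: {m.target}")
    lines += ["", "## Induced slots", "",
              "| slot | cardinality | range | inherited from | description |",
              "|---|---|---|---|---|"]
    for slot in ms.induced[cname]:
        sources = []
        for source_class, _, _ in slot.provenance:
            label = cname if source_class == "<schema>" else source_class
            if label not in sources:
                sources.append(label)
        origin = ", ".join(sources) or cname
        lines.append(
            f"| {slot.name} | {_cardinality_token(slot)} | "
            f"{ms.effective_range(slot)} | {origin} | "
            f"{slot.definition.description or ''} |"
        )
    return "\n".join(lines) + "\n"


def _diagram(ms: MaterializedSchema) -> str:
    """Class-relationship edge list in a plain text graph notation."""
    edges = []
    for cname, cls in ms.source.classes.items():
        if cls.is_a:
            edges.append(f"({cname})-[is_a]->({cls.is_a})")
        for mixin in cls.mixins:
            edges.append(f"({cname})-[mixin]->({mixin})")
        for slot in ms.induced[cname]:
            rng = ms.effective_range(slot)
            if ms.range_kind(rng) in ("class", "enum"):
                edges.append(f"({cname})-[{slot.name}]->({rng})")
    return "\n".join(edges) + ("\n" if edges else "")


def gen_markdown_docs(ms: MaterializedSchema) -> GeneratedArtifact:
    """Markdown pages: one per class/slot/enum/type, an index, a diagram.

    Class pages list the induced slots with cardinality, range, description
    and inheritance provenance; the diagram file holds the is_a and
    slot-range edge list.
    """
    files: dict[str, str] = {}
    for cname in ms.source.classes:
        files[f"{cname}.md"] = _class_page(ms, cname)
    files.update(_slot_pages(ms))
    for ename, enum in ms.source.enums.items():
        lines = [f"# Enum: {ename}", ""]
        if enum.description:
            lines += [enum.description, ""]
        lines += ["| value | meaning | description |", "|---|---|---|"]
        for pv in enum.permissible_values.values():
            lines.append(
                f"| {pv.text} | {pv.meaning or ''} | {pv.description or ''} |"
            )
        files[f"{ename}.md"] = "\n".join(lines) + "\n"
    for tname, t in ms.source.types.items():
        lines = [f"# Type: {tname}", "", f"* base: {t.base}"]
        if t.uri:
            lines.append(f"* uri: {t.uri}")
        if t.pattern:
            lines.append(f"* pattern: `{t.pattern}`")
        files[f"{tname}.md"] = "\n".join(lines) + "\n"

    index = [f"# {ms.source.title or ms.source.name or 'Schema'}", ""]
    if ms.source.id:
        index.append(f"Schema id: <{ms.source.id}>")
    for heading, names in [
        ("Classes", list(ms.source.classes)),
        ("Slots", [f[:-3] for f in _slot_pages(ms)]),
        ("Enums", list(ms.source.enums)),
        ("Types", list(ms.source.types)),
    ]:
        if names:
            index += ["", f"## {heading}", ""]
            index += [f"* [{n}]({n}.md)" for n in names]
    files["index.md"] = "\n".join(index) + "\n"
    files["schema_diagram.txt"] = _diagram(ms)
    return GeneratedArtifact(kind="markdown_docs", files=files)


# --- SQL DDL ------------------------------------------------------------------

def snake_case(name: str) -> str:
    """CamelCase / mixed name -> snake_case SQL identifier."""
    s = re.sub(r"(?<=[a-z0-9])(?=[A-Z])", "_", name)
    s = re.sub(r"(?<=[A-Z])(?=[A-Z][a-z])", "_", s)
    s = re.sub(r"[^A-Za-z0-9]+", "_", s)
    return s.strip("_").lower()


_SQL_TYPES = {"float": "REAL", "integer": "INTEGER", "boolean": "BOOLEAN"}


def _sql_type(ms: MaterializedSchema, rng: str) -> str:
    if ms.range_kind(rng) == "type":
        return _SQL_TYPES.get(ms.range_base(rng), "TEXT")
    return "TEXT"


def gen_sql_ddl(ms: MaterializedSchema) -> GeneratedArtifact:
    """Minimal DDL: one table per non-abstract class.

    Identifier slot becomes the PRIMARY KEY (a surrogate key is synthesized,
    with a loss-report warning, when a class declares none); required slots
    NOT NULL; enum ranges get a CHECK over the permissible values;
    multivalued slots become an auxiliary link table (owner_id, value).
    Class-ranged slots store the referenced instance's identifier as TEXT.
    """
    losses: list[dict] = []
    name_map: dict[str, str] = {}
    statements: list[str] = []
    schema_name = ms.source.name or "schema"

    for cname, cls in ms.source.classes.items():
        if cls.abstract:
            continue
        table = snake_case(cname)
        name_map[cname] = table
        id_slot = ms.identifier_slot[cname]
        columns: list[str] = []
        link_tables: list[str] = []
        if id_slot is None:
            columns.append(f"{table}_pk INTEGER PRIMARY KEY")
            losses.append({
                "code": "no_identifier",
                "element": cname,
                "detail": f"class has no identifier slot; surrogate key "
                          f"{table}_pk synthesized",
            })
            owner_ref = f"{table}_pk"
        else:
            owner_ref = snake_case(id_slot)
        for slot in ms.induced[cname]:
            col = snake_case(slot.name)
            name_map[f"{cname}.{slot.name}"] = col
            rng = ms.effective_range(slot)
            if slot.multivalued:
                link = f"{table}_{col}"
                link_tables.append(
                    f"CREATE TABLE {link} (\n"
                    f"  {table}_id TEXT NOT NULL,\n"
                    f"  value {_sql_type(ms, rng)}"
                    f"{_enum_check(ms, rng, 'value')}\n"
                    f");"
                )
                losses.append({
                    "code": "multivalued_link_table",
                    "element": f"{cname}.{slot.name}",
                    "detail": f"multivalued slot normalized into link table "
                              f"{link}",
                })
                continue
            parts = [f"{col} {_sql_type(ms, rng)}"]
            if slot.identifier:
                parts.append("PRIMARY KEY")
            elif slot.required:
                parts.append("NOT NULL")
            check = _enum_check(ms, rng, col)
            columns.append(" ".join(parts) + check)
            if ms.range_kind(rng) == "class":
                losses.append({
                    "code": "class_range_as_text",
                    "element": f"{cname}.{slot.name}",
                    "detail": f"stores the identifier of a {rng} instance "
                              "as TEXT (no FOREIGN KEY emitted)",
                })
        statements.append(
            f"CREATE TABLE {table} (\n  " + ",\n  ".join(columns) + "\n);"
        )
        statements.extend(link_tables)

    ddl = "\n\n".join(statements) + ("\n" if statements else "")
    return GeneratedArtifact(
        kind="sql_ddl",
        files={
            f"{schema_name}.sql": ddl,
            f"{schema_name}.sql.loss.json": _loss_json(
                "sql_ddl", losses, {"name_map": name_map}
            ),
        },
    )


def _enum_check(ms: MaterializedSchema, rng: str, column: str) -> str:
    if ms.range_kind(rng) != "enum":
        return ""
    values = ", ".join(
        "'" + text.replace("'", "''") + "'"
        for text in ms.source.enums[rng].permissible_values
    )
    return f" CHECK ({column} IN ({values}))"
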