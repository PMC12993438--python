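"""Validate instance documents against a materialized schema.

All data problems become located, severity-tagged issues in a
:class:`ValidationReport`; the only exception a caller sees is
:class:`UnknownClass` for a document claiming a class the schema lacks.

Checks per induced slot: required-present, list-shape versus multivalued,
scalar type conformance (integers are accepted where a float is expected —
spreadsheets routinely store 30 for 30.0 — everything else is strict),
enum membership (exact permissible-value text, optionally case-insensitive
per enum), regex pattern (full match), recursion into class-ranged values,
and unknown-slot handling (closed-world: ERROR; open-world: WARNING).

Empty strings are treated as "value absent": flagged only when the slot is
required. Collections additionally get identifier-uniqueness checking.

The module also defines a small plugin contract so alternative engines
(e.g. one driving a generated JSON Schema) can be swapped in: an engine has
a ``name``, ``prepare(ms, class_name) -> artifact`` and
``check(artifact, doc) -> bool``.
"""

from __future__ import annotations

import datetime
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Optional

from .compiler import InducedSlot, MaterializedSchema
from .errors import UnknownClass
from .metamodel import is_curie, is_uri

__all__ = [
    "Severity",
    "InstanceDocument",
    "ValidationIssue",
    "ValidationReport",
    "validate_instance",
    "validate_collection",
    "documents_from_rows",
    "NativeEngine",
    "JsonSchemaEngine",
]


class Severity(Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


@dataclass
class InstanceDocument:
    """A typed record: the class it instantiates plus its slot values.

    Values are scalars, lists, nested documents, or plain dicts (coerced to
    nested documents during validation using the slot's range class).
    """

    class_name: str
    values: dict[str, Any] = field(default_factory=dict)

    def to_plain(self) -> dict:
        def conv(v):
            if isinstance(v, InstanceDocument):
                return v.to_plain()
            if isinstance(v, list):
                return [conv(x) for x in v]
            return v

        return {k: conv(v) for k, v in self.values.items()}


@dataclass(frozen=True)
class ValidationIssue:
    severity: Severity
    check: str
    path: str
    message: str
    value: str = ""

    def as_dict(self) -> dict:
        return {
            "severity": self.severity.value,
            "check": self.check,
            "path": self.path,
            "message": self.message,
            "value": self.value,
        }


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not any(i.severity is Severity.ERROR for i in self.issues)

    def count(self, severity: Severity) -> int:
        return sum(1 for i in self.issues if i.severity is severity)

    def extend(self, other: "ValidationReport") -> None:
        self.issues.extend(other.issues)

    def to_json(self) -> str:
        return json.dumps(
            {
                "valid": self.valid,
                "errors": self.count(Severity.ERROR),
                "warnings": self.count(Severity.WARNING),
                "issues": [i.as_dict() for i in self.issues],
            },
            indent=2,
        )

    def to_text(self) -> str:
        if not self.issues:
            return "OK: no issues\n"
        lines = [
            f"{i.severity.value} [{i.check}] {i.path}: {i.message}"
            for i in self.issues
        ]
        lines.append(
            f"{self.count(Severity.ERROR)} error(s), "
            f"{self.count(Severity.WARNING)} warning(s)"
        )
        return "\n".join(lines) + "\n"


def _absent(value: Any) -> bool:
    return value is None or (isinstance(value, str) and value.strip() == "")


def _check_scalar(base: str, value: Any) -> Optional[str]:
    """Return a problem description, or None if *value* conforms to *base*."""
    if base == "string":
        if not isinstance(value, str):
            return f"expected string, got {type(value).__name__}"
    elif base == "integer":
        if isinstance(value, bool) or not isinstance(value, int):
            return f"expected integer, got {type(value).__name__}"
    elif base == "float":
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            return f"expected number, got {type(value).__name__}"
    elif base == "boolean":
        if not isinstance(value, bool):
            return f"expected boolean, got {type(value).__name__}"
    elif base == "uri":
        if not isinstance(value, str) or not is_uri(value):
            return f"expected URI, got {value!r}"
    elif base == "uriorcurie":
        if not isinstance(value, str) or not (is_uri(value) or is_curie(value)):
            return f"expected URI or CURIE, got {value!r}"
    elif base == "date":
        if not isinstance(value, str):
            return f"expected ISO date string, got {type(value).__name__}"
        try:
            datetime.date.fromisoformat(value)
        except ValueError:
            return f"not an ISO date: {value!r}"
    elif base == "datetime":
        if not isinstance(value, str):
            return f"expected ISO datetime string, got {type(value).__name__}"
        try:
            datetime.datetime.fromisoformat(value)
        except ValueError:
            return f"not an ISO datetime: {value!r}"
    return None


def _validate_value(
    ms: MaterializedSchema,
    slot: InducedSlot,
    value: Any,
    path: str,
    issues: list[ValidationIssue],
    open_world: bool,
) -> None:
    rng = ms.effective_range(slot)
    kind = ms.range_kind(rng)
    if kind == "class":
        if isinstance(value, dict):
            value = InstanceDocument(class_name=rng, values=value)
        if not isinstance(value, InstanceDocument):
            issues.append(
                ValidationIssue(
                    Severity.ERROR,
                    "type",
                    path,
                    f"expected nested {rng} object",
                    repr(value),
                )
            )
            return
        sub = validate_instance(ms, value, open_world=open_world)
        for issue in sub.issues:
            issues.append(
                ValidationIssue(
                    issue.severity, issue.check, path + issue.path,
                    issue.message, issue.value,
                )
            )
        return
    if isinstance(value, (dict, InstanceDocument, list)):
        issues.append(
            ValidationIssue(
                Severity.ERROR, "type", path,
                f"expected scalar of range {rng}", repr(value),
            )
        )
        return
    if kind == "enum":
        enum = ms.source.enums[rng]
        texts = list(enum.permissible_values)
        hit = (
            str(value) in texts
            if not enum.case_insensitive
            else str(value).casefold() in {t.casefold() for t in texts}
        )
        if not hit:
            issues.append(
                ValidationIssue(
                    Severity.ERROR,
                    "enum_miss",
                    path,
                    f"value not among permissible values of {rng}: {texts}",
                    str(value),
                )
            )
        return
    # primitive / user type
    problem = _check_scalar(ms.range_base(rng), value)
    if problem is not None:
        issues.append(
            ValidationIssue(Severity.ERROR, "type", path, problem, repr(value))
        )
        return
    patterns = []
    if slot.definition.pattern:
        patterns.append(slot.definition.pattern)
    user_type = ms.source.types.get(rng)
    if user_type is not None and user_type.pattern:
        patterns.append(user_type.pattern)
    for pattern in patterns:
        if isinstance(value, str) and re.fullmatch(pattern, value) is None:
            issues.append(
                ValidationIssue(
                    Severity.ERROR, "pattern", path,
                    f"value does not match pattern {pattern!r}", str(value),
                )
            )


def validate_instance(
    ms: MaterializedSchema,
    doc: InstanceDocument,
    open_world: bool = False,
) -> ValidationReport:
    """Validate one document; issue paths are slash-delimited from its root."""
    if doc.class_name not in ms.source.classes:
        raise UnknownClass(f"document class {doc.class_name!r} not in schema")
    issues: list[ValidationIssue] = []
    slots = {s.name: s for s in ms.induced[doc.class_name]}

    for name, slot in slots.items():
        path = f"/{name}"
        value = doc.values.get(name)
        if _absent(value):
            if slot.required:
                issues.append(
                    ValidationIssue(
                        Severity.ERROR, "required_missing", path,
                        f"required slot {name!r} is missing or empty",
                    )
                )
            continue
        if slot.multivalued:
            if not isinstance(value, list):
                issues.append(
                    ValidationIssue(
                        Severity.ERROR, "shape", path,
                        "multivalued slot expects a list", repr(value),
                    )
                )
                continue
            for i, item in enumerate(value):
                _validate_value(ms, slot, item, f"{path}/{i}", issues, open_world)
        else:
            if isinstance(value, list):
                issues.append(
                    ValidationIssue(
                        Severity.ERROR, "shape", path,
                        "single-valued slot got a list", repr(value),
                    )
                )
                continue
            _validate_value(ms, slot, value, path, issues, open_world)

    severity = Severity.WARNING if open_world else Severity.ERROR
    for name in doc.values:
        if name not in slots:
            issues.append(
                ValidationIssue(
                    severity, "unknown_slot", f"/{name}",
                    f"slot {name!r} is not defined for class {doc.class_name}",
                )
            )
    return ValidationReport(issues=issues)


def validate_collection(
    ms: MaterializedSchema,
    docs: list[InstanceDocument],
    open_world: bool = False,
) -> ValidationReport:
    """Validate a document list; adds identifier-uniqueness checking.

    Issue paths gain a leading ``/<index>`` segment. When the documents'
    class has no identifier slot this degrades to per-document validation.
    """
    report = ValidationReport()
    seen: dict[tuple[str, Any], int] = {}
    for i, doc in enumerate(docs):
        sub = validate_instance(ms, doc, open_world=open_world)
        for issue in sub.issues:
            report.issues.append(
                ValidationIssue(
                    issue.severity, issue.check, f"/{i}{issue.path}",
                    issue.message, issue.value,
                )
            )
        id_slot = ms.identifier_slot.get(doc.class_name)
        if id_slot is None:
            continue
        value = doc.values.get(id_slot)
        if _absent(value):
            continue
        key = (doc.class_name, value)
        if key in seen:
            report.issues.append(
                ValidationIssue(
                    Severity.ERROR,
                    "duplicate_identifier",
                    f"/{i}/{id_slot}",
                    f"identifier {value!r} already used by document "
                    f"{seen[key]}",
                    str(value),
                )
            )
        else:
            seen[key] = i
    return report


def documents_from_rows(
    class_name: str,
    header: list[str],
    rows: list[list[str]],
    ms: Optional[MaterializedSchema] = None,
) -> list[InstanceDocument]:
    """Map flat TSV/CSV rows (header = slot names) to documents.

    When a materialized schema is given, cells are coerced to the slot's
    primitive base where that can be done losslessly (int/float/bool
    literals); unparseable cells are left as strings for the validator to
    flag. Empty cells become absent slots.
    """
    slot_bases: dict[str, str] = {}
    multivalued: set[str] = set()
    if ms is not None and class_name in ms.induced:
        for slot in ms.induced[class_name]:
            rng = ms.effective_range(slot)
            if ms.range_kind(rng) == "type":
                slot_bases[slot.name] = ms.range_base(rng)
            if slot.multivalued:
                multivalued.add(slot.name)

    def coerce(name: str, cell: str) -> Any:
        base = slot_bases.get(name)
        text = cell.strip()
        if base == "integer":
            try:
                return int(text)
            except ValueError:
                return text
        if base == "float":
            try:
                return float(text)
            except ValueError:
                return text
        if base == "boolean":
            lowered = text.lower()
            if lowered in ("true", "false"):
                return lowered == "true"
            return text
        return text

    docs = []
    for row in rows:
        values: dict[str, Any] = {}
        for name, cell in zip(header, row):
            if cell is None or str(cell).strip() == "":
                continue
            if name in multivalued:
                values[name] = [coerce(name, part) for part in str(cell).split("|")]
            else:
                values[name] = coerce(name, str(cell))
        docs.append(InstanceDocument(class_name=class_name, values=values))
    return docs


# --- engine plugin contract ---------------------------------------------------

class NativeEngine:
    """Reference engine: drives :func:`validate_instance` directly."""

    name = "native"

    def __init__(self, open_world: bool = False):
        self.open_world = open_world

    def prepare(self, ms: MaterializedSchema, class_name: str):
        if class_name not in ms.source.classes:
            raise UnknownClass(class_name)
        return (ms, class_name)

    def check(self, artifact, doc: InstanceDocument) -> bool:
        ms, _ = artifact
        return validate_instance(ms, doc, open_world=self.open_world).valid


class JsonSchemaEngine:
    """Engine backed by the generated JSON Schema.

    Independent route: the document is reduced to plain JSON and judged by
    the ``jsonschema`` library against the artifact produced by
    :func:`schemakit.generators.gen_json_schema`. Identifier uniqueness is
    outside JSON Schema's expressiveness and is not checked here.
    """

    name = "json_schema"

    def __init__(self, open_world: bool = False):
        self.open_world = open_world

    def prepare(self, ms: MaterializedSchema, class_name: str):
        import jsonschema

        from .generators import gen_json_schema

        artifact = gen_json_schema(ms, class_name, open_world=self.open_world)
        schema_text = next(
            content for name, content in artifact.files.items()
            if name.endswith(".schema.json")
        )
        return jsonschema.Draft202012Validator(json.loads(schema_text))

    def check(self, artifact, doc: InstanceDocument) -> bool:
        return artifact.is_valid(doc.to_plain())
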