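"""Tabular schema authoring and bootstrap.

Two workflows:

* **schemasheets**: a spreadsheet whose second row is a ``>``-prefixed
  *directive row* mapping columns to metamodel fields (``class``, ``slot``,
  ``cardinality``, ``required``, ``range``, ``is_a``, ``description``).
  Each data row declares a class (class cell only) or attaches a slot to a
  class (both cells). Converted to and from :class:`SchemaDefinition`.

* **inference**: bootstrap a schema from a raw data table by scanning
  column values — all-integer columns become ``integer`` slots, low-
  cardinality repetitive text columns become enumerations, and columns
  with few blanks become required.

Cardinality/required interplay: a multiplicity of ``1`` (min >= 1) implies
required; an explicit ``FALSE`` in the required column then is a hard
contradiction. The printed convention of pairing ``0..1`` with required
TRUE is accepted — the required column wins for the required flag while
the cardinality's maximum governs multivaluedness.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import Optional

from .errors import (
    BlankElementName,
    CardinalityRequiredConflict,
    EmptyTable,
    MissingDirectiveRow,
    UnknownDirectiveToken,
)
from .generators import snake_case
from .metamodel import Cardinality, parse_cardinality
from .schema_io import (
    ClassDefinition,
    EnumDefinition,
    PermissibleValue,
    SchemaDefinition,
    SlotDefinition,
)

__all__ = [
    "SheetTable",
    "SheetConversion",
    "InferenceOptions",
    "read_sheet",
    "write_sheet",
    "sheet_to_schema",
    "convert_sheet",
    "schema_to_sheet",
    "infer_schema_from_table",
]

DIRECTIVE_VOCABULARY = (
    "class",
    "slot",
    "cardinality",
    "required",
    "range",
    "is_a",
    "description",
)

DEFAULT_SHEET_ID = "https://example.org/sheet-schema"


@dataclass
class SheetTable:
    """A parsed spreadsheet: header labels, directive tokens, string rows."""

    header: list[str]
    directive: list[str]
    rows: list[list[str]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.directive) != len(self.header):
            raise MissingDirectiveRow(
                f"directive row has {len(self.directive)} cells, header has "
                f"{len(self.header)}"
            )


@dataclass
class SheetConversion:
    """Result of a sheet -> schema conversion.

    ``cardinalities`` retains the parsed multiplicity per (class, slot) —
    information the converted slot flags alone cannot reconstruct (the
    required column may override the multiplicity's minimum).
    """

    schema: SchemaDefinition
    cardinalities: dict[tuple[str, str], Cardinality] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def read_sheet(text: str, dialect: str = "tsv") -> SheetTable:
    """Parse TSV (default) or CSV text into a :class:`SheetTable`.

    The first row is the human-readable header; the first ``>``-prefixed
    row is the directive; further all-blank ``>`` rows are tolerated and
    skipped (spreadsheets often carry an empty second directive row).
    """
    delimiter = "\t" if dialect == "tsv" else ","
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    raw = [row for row in reader if any(cell.strip() for cell in row) or row]
    if not raw:
        raise MissingDirectiveRow("empty table")
    header = [cell.strip() for cell in raw[0]]
    directive: Optional[list[str]] = None
    rows: list[list[str]] = []
    for row in raw[1:]:
        cells = [cell.strip() for cell in row]
        cells += [""] * (len(header) - len(cells))
        if cells and cells[0].startswith(">"):
            tokens = [cells[0][1:].strip()] + cells[1:]
            if all(t == "" for t in tokens):
                continue  # decorative blank directive row
            if directive is None:
                directive = tokens
            continue
        if any(cells):
            rows.append(cells[: len(header)])
    if directive is None:
        raise MissingDirectiveRow("no '>'-prefixed directive row found")
    for token in directive:
        if token and token not in DIRECTIVE_VOCABULARY:
            raise UnknownDirectiveToken(
                f"directive token {token!r} not in {DIRECTIVE_VOCABULARY}"
            )
    return SheetTable(header=header, directive=directive, rows=rows)


def write_sheet(table: SheetTable, dialect: str = "tsv") -> str:
    delimiter = "\t" if dialect == "tsv" else ","
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    writer.writerow(table.header)
    writer.writerow([">" + table.directive[0]] + table.directive[1:])
    for row in table.rows:
        writer.writerow(row)
    return buf.getvalue()


def _column(table: SheetTable, token: str) -> Optional[int]:
    try:
        return table.directive.index(token)
    except ValueError:
        return None


def _parse_required_cell(cell: str) -> Optional[bool]:
    text = cell.strip().lower()
    if text == "":
        return None
    if text == "true":
        return True
    if text == "false":
        return False
    raise CardinalityRequiredConflict(
        f"required cell must be TRUE/FALSE or blank, got {cell!r}"
    )


def convert_sheet(
    table: SheetTable,
    base: Optional[dict] = None,
) -> SheetConversion:
    """Convert a directive-row table to a schema, keeping parse records.

    *base* supplies schema metadata (``id``, ``name``, ...); a placeholder
    id is used when absent. Classes referenced by slot rows but never
    declared on their own row are created implicitly.
    """
    base = dict(base or {})
    schema = SchemaDefinition(
        id=base.pop("id", DEFAULT_SHEET_ID),
        name=base.pop("name", "sheet_schema"),
        title=base.pop("title", None),
        license=base.pop("license", None),
    )
    conv = SheetConversion(schema=schema)

    cols = {token: _column(table, token) for token in DIRECTIVE_VOCABULARY}
    if cols["class"] is None:
        raise UnknownDirectiveToken("directive row must include a 'class' column")

    def cell(row: list[str], token: str) -> str:
        idx = cols[token]
        return row[idx].strip() if idx is not None and idx < len(row) else ""

    for row_no, row in enumerate(table.rows, start=1):
        class_name = cell(row, "class")
        slot_name = cell(row, "slot")
        if not class_name and not slot_name:
            raise BlankElementName(f"row {row_no}: no class or slot name")
        if not class_name:
            raise BlankElementName(
                f"row {row_no}: slot {slot_name!r} has no owning class"
            )
        cls = schema.classes.get(class_name)
        if cls is None:
            cls = ClassDefinition(name=class_name)
            schema.classes[class_name] = cls
        if not slot_name:
            # class-declaration row
            if cell(row, "description"):
                cls.description = cell(row, "description")
            if cell(row, "is_a"):
                cls.is_a = cell(row, "is_a")
            continue
        slot = SlotDefinition(name=slot_name)
        if cell(row, "description"):
            slot.description = cell(row, "description")
        if cell(row, "range"):
            slot.range = cell(row, "range")
        if cell(row, "is_a"):
            slot.annotations["is_a"] = cell(row, "is_a")
            conv.warnings.append(
                f"row {row_no}: slot-level is_a {cell(row, 'is_a')!r} kept as "
                "an annotation"
            )
        required_flag = _parse_required_cell(cell(row, "required"))
        card_token = cell(row, "cardinality")
        card: Optional[Cardinality] = None
        if card_token:
            card = parse_cardinality(card_token)
            conv.cardinalities[(class_name, slot_name)] = card
            if card.min >= 1 and required_flag is False:
                raise CardinalityRequiredConflict(
                    f"row {row_no}: cardinality {card_token!r} implies "
                    "required but the required column says FALSE"
                )
            slot.multivalued = card.multivalued
        if required_flag is not None:
            slot.required = required_flag
        elif card is not None and card.min >= 1:
            slot.required = True
        cls.attributes[slot_name] = slot
    return conv


def sheet_to_schema(table: SheetTable, base: Optional[dict] = None) -> SchemaDefinition:
    """Thin wrapper over :func:`convert_sheet` returning only the schema."""
    return convert_sheet(table, base).schema


#: Slot fields expressible in the directive vocabulary.
_EXPRESSIBLE = ("description", "range", "required", "multivalued")


def schema_to_sheet(schema: SchemaDefinition) -> tuple[SheetTable, list[str]]:
    """Export to tabular form: one class row per class, one row per slot.

    Returns the table plus a list of lossy-export warnings for features the
    directive vocabulary cannot carry (patterns, URIs, identifiers, enum
    and type definitions, prefixes...).
    """
    warnings: list[str] = []
    tokens = list(DIRECTIVE_VOCABULARY)
    rows: list[list[str]] = []

    def slot_row(class_name: str, slot: SlotDefinition) -> list[str]:
        if slot.multivalued is None:
            card = ""
        elif slot.multivalued:
            card = "1..*" if slot.required else "0..*"
        else:
            card = "1" if slot.required else "0..1"
        required_cell = "" if slot.required is None else str(slot.required).upper()
        for fname in ("pattern", "slot_uri", "unit", "identifier"):
            if getattr(slot, fname):
                warnings.append(
                    f"slot {class_name}.{slot.name}: {fname} not expressible "
                    "in sheet form"
                )
        if slot.mappings:
            warnings.append(
                f"slot {class_name}.{slot.name}: mappings not expressible "
                "in sheet form"
            )
        return [
            class_name,
            slot.name,
            card,
            required_cell,
            slot.range or "",
            slot.annotations.get("is_a", ""),
            slot.description or "",
        ]

    for cname, cls in schema.classes.items():
        rows.append(
            [cname, "", "", "", "", cls.is_a or "", cls.description or ""]
        )
        for ref in cls.slots:
            if ref in schema.slots:
                warnings.append(
                    f"class {cname}: schema-level slot {ref!r} flattened into "
                    "a class-local row"
                )
                rows.append(slot_row(cname, schema.slots[ref]))
        for slot in cls.attributes.values():
            rows.append(slot_row(cname, slot))
    for category, names in [
        ("enum", list(schema.enums)),
        ("type", list(schema.types)),
    ]:
        for name in names:
            warnings.append(
                f"{category} {name!r} cannot be defined in sheet form "
                "(referenced by range name only)"
            )
    return SheetTable(header=tokens, directive=tokens, rows=rows), warnings


# --- schema inference from raw data tables ------------------------------------

@dataclass
class InferenceOptions:
    """Heuristics for bootstrapping a schema from a data table.

    ``enum_max_distinct`` / ``enum_min_repetition``: a non-numeric column
    becomes an enumeration when it has at most that many distinct values
    and at least that many rows per distinct value. A slot is required when
    its blank fraction is below ``required_blank_threshold``.
    """

    class_name: str = "InferredClass"
    schema_id: str = "https://example.org/inferred-schema"
    schema_name: str = "inferred_schema"
    enum_max_distinct: int = 10
    enum_min_repetition: float = 1.5
    required_blank_threshold: float = 0.10


_INT_RE = re.compile(r"^[+-]?\d+$")
_BOOL_VALUES = {"true", "false"}


def _is_float(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def infer_schema_from_table(
    header: list[str],
    rows: list[list[str]],
    options: Optional[InferenceOptions] = None,
) -> SchemaDefinition:
    """Bootstrap a one-class schema from raw string records.

    Deterministic and insensitive to row order: enumeration values are
    sorted, and all per-column statistics are permutation-invariant.
    """
    options = options or InferenceOptions()
    if not rows:
        raise EmptyTable("schema inference needs at least one data row")
    schema = SchemaDefinition(id=options.schema_id, name=options.schema_name)
    cls = ClassDefinition(
        name=options.class_name,
        description="Class inferred from a data table.",
    )
    schema.classes[options.class_name] = cls

    for col, label in enumerate(header):
        slot_name = (
            label if re.fullmatch(r"[a-z][a-z0-9_]*", label) else snake_case(label)
        ) or f"column_{col + 1}"
        cells = [row[col].strip() if col < len(row) else "" for row in rows]
        values = [c for c in cells if c != ""]
        blank_fraction = 1.0 - len(values) / len(cells)
        rng = "string"
        if values:
            if all(_INT_RE.match(v) for v in values):
                rng = "integer"
            elif all(_is_float(v) for v in values):
                rng = "float"
            elif all(v.lower() in _BOOL_VALUES for v in values):
                rng = "boolean"
            else:
                distinct = sorted(set(values))
                repetition = len(values) / len(distinct)
                if (
                    len(distinct) <= options.enum_max_distinct
                    and repetition >= options.enum_min_repetition
                ):
                    enum_name = (
                        "".join(p.capitalize() for p in slot_name.split("_"))
                        + "Enum"
                    )
                    schema.enums[enum_name] = EnumDefinition(
                        name=enum_name,
                        description=f"Values observed in column {label!r}.",
                        permissible_values={
                            v: PermissibleValue(text=v) for v in distinct
                        },
                    )
                    rng = enum_name
        slot = SlotDefinition(
            name=slot_name,
            description=f"Inferred from column {label!r}.",
            range=rng,
        )
        if blank_fraction < options.required_blank_threshold:
            slot.required = True
        cls.attributes[slot_name] = slot
    return schema
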