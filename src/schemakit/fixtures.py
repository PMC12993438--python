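"""Worked examples and synthetic data.

Everything here is generated or transcribed in-package so the whole
toolkit is testable and demonstrable offline:

* a microbiome ``Sample`` schema (classes Sample/Study, a controlled
  environment-type vocabulary with ENVO term meanings);
* the same Sample/Study model in tabular (schemasheets) form;
* a legacy variant with a fused ``position`` field plus the transformation
  spec that modernizes it (split position -> latitude/longitude, rename
  environment_type -> sample_type);
* a deterministic generator of *messy* sample spreadsheets — mixed-unit
  depth strings, free-text environment terms, blank cells, fused
  lat/lon cells — with the clean ground truth and the injected-fault
  inventory retained;
* the harmonizer that turns such a table into schema-conformant documents
  (unit conversion to metres, position splitting, vocabulary matching,
  identifier minting) with per-cell provenance;
* random conformant-document generation and single-fault corruption used
  by the validation test harnesses.

The MIXS prefix base URI and all ENVO meaning CURIEs are fixture
constants chosen for the examples, as are the unit and synonym tables.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Any, Optional

from .compiler import MaterializedSchema, materialize
from .errors import CastError, SplitArityMismatch
from .mapspec import Split, TransformSpec, transform_instance
from .schema_io import SchemaDefinition, parse_schema
from .validator import (
    InstanceDocument,
    Severity,
    ValidationIssue,
    ValidationReport,
    validate_instance,
)

__all__ = [
    "SAMPLE_SCHEMA_YAML",
    "LEGACY_POSITION_SCHEMA_YAML",
    "POSITION_SPLIT_SPEC_YAML",
    "SAMPLE_STUDY_SHEET_TSV",
    "UNIT_TABLE",
    "ENV_SYNONYMS",
    "sample_schema",
    "sample_schema_materialized",
    "MessyTable",
    "HarmonizationResult",
    "generate_messy_samples",
    "harmonize_samples",
    "random_documents",
    "corrupt_document",
]

#: Environment-sample schema used throughout the docs and tests.
#: Enum values carry ENVO meaning CURIEs; the latitude slot reuses the
#: schema.org property, depth the MIxS depth slot URI.
SAMPLE_SCHEMA_YAML = """\
id: https://example.org/sample-schema
name: sample_schema
title: Microbiome Sample Schema
license: https://creativecommons.org/publicdomain/zero/1.0/
prefixes:
  samp: https://example.org/sample-schema/
  ENVO: http://purl.obolibrary.org/obo/ENVO_
  OBI: http://purl.obolibrary.org/obo/OBI_
  schema: http://schema.org/
  MIXS: https://w3id.org/mixs/
default_range: string
enums:
  EnvironmentTypeEnum:
    description: Controlled vocabulary for the environment a sample was taken from.
    permissible_values:
      soil:
        description: Terrestrial soil environment.
        meaning: ENVO:00001998
      water:
        description: Aquatic environment.
        meaning: ENVO:00002006
      air:
        description: Atmospheric environment.
        meaning: ENVO:00002005
      sediment:
        description: Particulate matter deposited under water.
        meaning: ENVO:00002007
classes:
  Sample:
    description: A material sample collected from an environment.
    class_uri: OBI:0000747
    attributes:
      id:
        description: Unique, resolvable identifier of the sample.
        identifier: true
        required: true
        range: uriorcurie
      latitude:
        description: The latitude of the sample location in decimal degrees.
        range: float
        required: true
        slot_uri: schema:latitude
      longitude:
        description: The longitude of the sample location in decimal degrees.
        range: float
        required: true
        slot_uri: schema:longitude
      depth:
        description: Depth below the surface at which the sample was taken, in metres.
        range: float
        unit: m
        slot_uri: MIXS:0000009
      environment_type:
        description: The environment from which the sample was taken.
        range: EnvironmentTypeEnum
  Study:
    description: An investigation that collects and analyses samples.
    attributes:
      id:
        description: The unique identifier of a study.
        identifier: true
        required: true
        range: uriorcurie
      samples:
        description: Samples collected within this study.
        range: Sample
        multivalued: true
"""

#: Legacy schema with a fused "position" field and project-local naming.
LEGACY_POSITION_SCHEMA_YAML = """\
id: https://example.org/legacy-sample-schema
name: legacy_sample_schema
title: Legacy Sample Schema
prefixes:
  samp: https://example.org/sample-schema/
  ENVO: http://purl.obolibrary.org/obo/ENVO_
default_range: string
enums:
  EnvironmentTypeEnum:
    description: Controlled vocabulary for the environment a sample was taken from.
    permissible_values:
      soil:
        meaning: ENVO:00001998
      water:
        meaning: ENVO:00002006
      air:
        meaning: ENVO:00002005
      sediment:
        meaning: ENVO:00002007
classes:
  Sample:
    description: A material sample, legacy shape.
    attributes:
      id:
        description: Sample identifier.
        identifier: true
        required: true
        range: uriorcurie
      position:
        description: Fused "latitude, longitude" text.
        range: string
        required: true
      environment_type:
        description: The environment from which the sample was taken.
        range: EnvironmentTypeEnum
"""

#: Declarative migration of the legacy shape to the target terminology.
POSITION_SPLIT_SPEC_YAML = """\
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
"""

#: The Sample/Study model in directive-row tabular form. The multiplicity
#: cells deliberately use the two-dot-leader and ellipsis glyphs that
#: spreadsheet exports produce in place of "..".
SAMPLE_STUDY_SHEET_TSV = (
    "record\tfield\tmultiplicity\trequired\trange\tparents\tdesc\n"
    "> class\tslot\tcardinality\trequired\trange\tis_a\tdescription\n"
    ">\t\t\t\t\t\t\n"
    "Sample\t\t\t\t\t\t\n"
    "Sample\tlatitude\t0‥1\tTRUE\tfloat\t\tThe latitude of the sample location.\n"
    "Sample\tlongitude\t0‥1\tTRUE\tfloat\t\tThe longitude of the sample location.\n"
    "Sample\tenvironment_type\t0…1\t\tEnvironmentTypeEnum\t\tThe environment from which the sample was taken.\n"
    "Study\tid\t1\tTRUE\turiorcurie\t\tThe unique identifier of a study.\n"
)

#: Depth-unit conversion factors to metres.
UNIT_TABLE: dict[str, float] = {
    "m": 1.0,
    "meter": 1.0,
    "meters": 1.0,
    "cm": 0.01,
    "mm": 0.001,
    "ft": 0.3048,
    "foot": 0.3048,
    "feet": 0.3048,
    "in": 0.0254,
    "inch": 0.0254,
    "inches": 0.0254,
}

#: Free-text environment terms mapped to the controlled vocabulary.
ENV_SYNONYMS: dict[str, str] = {
    "dirt": "soil",
    "earth": "soil",
    "topsoil": "soil",
    "seawater": "water",
    "sea water": "water",
    "freshwater": "water",
    "aqua": "water",
    "atmosphere": "air",
    "ambient air": "air",
    "mud": "sediment",
    "silt": "sediment",
}

_ENV_TERMS = ("soil", "water", "air", "sediment")


def sample_schema() -> SchemaDefinition:
    return parse_schema(SAMPLE_SCHEMA_YAML)


def sample_schema_materialized() -> MaterializedSchema:
    return materialize(sample_schema())


# --- messy-table generation ---------------------------------------------------

@dataclass
class MessyTable:
    """A synthetic raw spreadsheet plus its generation ground truth.

    ``ground_truth[i]`` holds the clean document values row ``i`` encodes;
    ``faults`` is the injected-fault inventory as (row-ordinal, column,
    fault-kind) triples. Rows are rendered strings only.
    """

    header: list[str]
    rows: list[list[str]]
    ground_truth: list[dict] = field(default_factory=list)
    faults: list[tuple[int, str, str]] = field(default_factory=list)


#: Depth render dialects: (format, unit factor label). Only decimal metric
#: dialects are emitted so harmonization of unfaulted cells is exact.
_DEPTH_DIALECTS = (
    ("{v:g}", 1.0),          # bare number, metres implied
    ("{v:g} m", 1.0),
    ("{v:g}m", 1.0),
    ("{v:g} meters", 1.0),
    ("{v:g} cm", 100.0),
    ("{v:g}mm", 1000.0),
)

_DEFAULT_FAULT_RATES = {
    "blank": 0.0,
    "case": 0.0,
    "synonym": 0.0,
    "garbage_depth": 0.0,
    "garbage_env": 0.0,
}

_GARBAGE_DEPTHS = ("deep", "n/a", "??", "surface-ish")
_GARBAGE_ENVS = ("lava", "concrete", "zzz_unknown")


def generate_messy_samples(
    seed: int,
    n_rows: int,
    fault_rates: Optional[dict[str, float]] = None,
) -> MessyTable:
    """Deterministically generate a messy sample spreadsheet.

    Depth values are rendered in randomly chosen unit dialects, positions
    are fused "lat, lon" cells, and environment terms are clean vocabulary
    words unless faulted. Fault kinds (independent per eligible cell, each
    with the given probability): ``blank`` (any data cell), ``case`` /
    ``synonym`` (environment cell, repairable), ``garbage_depth`` /
    ``garbage_env`` (unrepairable). At most one fault is injected per
    cell. The clean values and the fault inventory are retained.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    rates = dict(_DEFAULT_FAULT_RATES)
    for key, p in (fault_rates or {}).items():
        if key not in rates:
            raise ValueError(f"unknown fault kind {key!r}")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"fault rate {key}={p} outside [0, 1]")
        rates[key] = p

    rng = random.Random(seed)
    header = ["position", "dep", "env"]
    rows: list[list[str]] = []
    truth: list[dict] = []
    faults: list[tuple[int, str, str]] = []

    for ordinal in range(1, n_rows + 1):
        depth = round(rng.uniform(0.05, 50.0), 3)
        lat = round(rng.uniform(-90.0, 90.0), 4)
        lon = round(rng.uniform(-180.0, 180.0), 4)
        env = rng.choice(_ENV_TERMS)
        truth.append(
            {
                "id": f"samp:{ordinal:04d}",
                "latitude": lat,
                "longitude": lon,
                "depth": depth,
                "environment_type": env,
            }
        )

        fmt, factor = rng.choice(_DEPTH_DIALECTS)
        dep_cell = fmt.format(v=round(depth * factor, 6))
        pos_cell = f"{lat!r}, {lon!r}"
        env_cell = env

        if rng.random() < rates["garbage_depth"]:
            dep_cell = rng.choice(_GARBAGE_DEPTHS)
            faults.append((ordinal, "dep", "garbage_depth"))
        elif rng.random() < rates["blank"]:
            dep_cell = ""
            faults.append((ordinal, "dep", "blank"))

        if rng.random() < rates["blank"]:
            pos_cell = ""
            faults.append((ordinal, "position", "blank"))

        if rng.random() < rates["garbage_env"]:
            env_cell = rng.choice(_GARBAGE_ENVS)
            faults.append((ordinal, "env", "garbage_env"))
        elif rng.random() < rates["blank"]:
            env_cell = ""
            faults.append((ordinal, "env", "blank"))
        elif rng.random() < rates["synonym"]:
            candidates = [s for s, c in ENV_SYNONYMS.items() if c == env]
            env_cell = rng.choice(candidates)
            faults.append((ordinal, "env", "synonym"))
        elif rng.random() < rates["case"]:
            env_cell = rng.choice((env.upper(), env.title(), env.capitalize()))
            faults.append((ordinal, "env", "case"))

        rows.append([pos_cell, dep_cell, env_cell])

    return MessyTable(header=header, rows=rows, ground_truth=truth,
                      faults=faults)


# --- harmonization ------------------------------------------------------------

@dataclass
class HarmonizationResult:
    """Outcome of cleaning a messy table against the Sample schema.

    ``clean_docs`` validate against the schema; ``rejected_docs`` carry at
    least one unrecovered error (their issues are in ``report``).
    ``provenance`` records, per cell, (row-ordinal, column, raw value,
    parsed value, action).
    """

    clean_docs: list[InstanceDocument] = field(default_factory=list)
    rejected_docs: list[InstanceDocument] = field(default_factory=list)
    report: ValidationReport = field(default_factory=ValidationReport)
    provenance: list[tuple[int, str, str, Any, str]] = field(
        default_factory=list
    )


_POSITION_SPLIT = TransformSpec(
    operations=[
        Split(
            class_name="Sample",
            source_slot="position",
            targets=["latitude", "longitude"],
            delimiter=",",
            target_ranges=["float", "float"],
        )
    ]
)


def _parse_depth(
    raw: str, unit_table: dict[str, float], default_unit: str
) -> float:
    text = raw.strip()
    i = len(text)
    while i > 0 and (text[i - 1].isalpha() or text[i - 1] == " "):
        i -= 1
    number, unit = text[:i].strip(), text[i:].strip().lower()
    if not unit:
        unit = default_unit
    if unit not in unit_table:
        raise ValueError(f"unknown depth unit {unit!r}")
    return round(float(number) * unit_table[unit], 3)


def harmonize_samples(
    table: MessyTable,
    ms: Optional[MaterializedSchema] = None,
    unit_table: Optional[dict[str, float]] = None,
    synonyms: Optional[dict[str, str]] = None,
    id_prefix: str = "samp",
    default_unit: str = "m",
) -> HarmonizationResult:
    """Clean a messy table into Sample documents, reporting what failed.

    Per row: depth strings are parsed against the unit table and converted
    to metres (3 decimals); the fused position cell is split through the
    declarative transformation engine; environment text is matched to the
    enum after case-folding and synonym lookup; a CURIE identifier
    ``<prefix>:<zero-padded ordinal>`` is minted. Unparseable cells become
    report issues and the row is emitted with that slot absent. Total: no
    exceptions for data problems.
    """
    ms = ms or sample_schema_materialized()
    unit_table = unit_table or UNIT_TABLE
    synonyms = {k.casefold(): v for k, v in (synonyms or ENV_SYNONYMS).items()}
    enum = ms.source.enums["EnvironmentTypeEnum"]
    vocab = {t.casefold(): t for t in enum.permissible_values}

    result = HarmonizationResult()
    col = {label: i for i, label in enumerate(table.header)}

    for ordinal, row in enumerate(table.rows, start=1):
        values: dict[str, Any] = {}
        issues: list[ValidationIssue] = []
        prov = result.provenance.append

        minted = f"{id_prefix}:{ordinal:04d}"
        values["id"] = minted
        prov((ordinal, "id", "", minted, "minted"))

        raw_dep = row[col["dep"]]
        if raw_dep.strip() == "":
            prov((ordinal, "dep", raw_dep, None, "blank_absent"))
        else:
            try:
                depth = _parse_depth(raw_dep, unit_table, default_unit)
                values["depth"] = depth
                prov((ordinal, "dep", raw_dep, depth, "converted"))
            except ValueError:
                issues.append(
                    ValidationIssue(
                        Severity.ERROR, "unit_parse", f"/{ordinal}/depth",
                        "cannot parse depth cell", raw_dep,
                    )
                )
                prov((ordinal, "dep", raw_dep, None, "rejected"))

        raw_pos = row[col["position"]]
        if raw_pos.strip() == "":
            prov((ordinal, "position", raw_pos, None, "blank_absent"))
        else:
            try:
                split_doc = transform_instance(
                    InstanceDocument("Sample", {"position": raw_pos}),
                    _POSITION_SPLIT,
                )
                values["latitude"] = split_doc.values["latitude"]
                values["longitude"] = split_doc.values["longitude"]
                prov((ordinal, "position", raw_pos,
                      (values["latitude"], values["longitude"]), "split"))
            except (SplitArityMismatch, CastError) as exc:
                issues.append(
                    ValidationIssue(
                        Severity.ERROR, "position_parse",
                        f"/{ordinal}/position", str(exc), raw_pos,
                    )
                )
                prov((ordinal, "position", raw_pos, None, "rejected"))

        raw_env = row[col["env"]]
        if raw_env.strip() == "":
            prov((ordinal, "env", raw_env, None, "blank_absent"))
        else:
            folded = raw_env.strip().casefold()
            if folded in vocab:
                term = vocab[folded]
                values["environment_type"] = term
                action = "matched" if raw_env.strip() == term else "case_folded"
                prov((ordinal, "env", raw_env, term, action))
            elif folded in synonyms:
                term = synonyms[folded]
                values["environment_type"] = term
                prov((ordinal, "env", raw_env, term, "synonym_mapped"))
            else:
                issues.append(
                    ValidationIssue(
                        Severity.ERROR, "enum_miss",
                        f"/{ordinal}/environment_type",
                        "term not in vocabulary or synonym table", raw_env,
                    )
                )
                prov((ordinal, "env", raw_env, None, "rejected"))

        doc = InstanceDocument(class_name="Sample", values=values)
        validation = validate_instance(ms, doc)
        for issue in validation.issues:
            issues.append(
                ValidationIssue(
                    issue.severity, issue.check, f"/{ordinal}{issue.path}",
                    issue.message, issue.value,
                )
            )
        result.report.issues.extend(issues)
        if any(i.severity is Severity.ERROR for i in issues):
            result.rejected_docs.append(doc)
        else:
            result.clean_docs.append(doc)
    return result


# --- random documents and fault injection -------------------------------------

def _random_value(ms: MaterializedSchema, rng_name: str, rng: random.Random,
                  depth: int) -> Any:
    kind = ms.range_kind(rng_name)
    if kind == "enum":
        return rng.choice(list(ms.source.enums[rng_name].permissible_values))
    if kind == "class":
        return random_documents(ms, rng_name, 1, rng, _depth=depth + 1)[0]
    base = ms.range_base(rng_name)
    if base == "integer":
        return rng.randint(-1000, 1000)
    if base == "float":
        return round(rng.uniform(-1000.0, 1000.0), 4)
    if base == "boolean":
        return rng.random() < 0.5
    if base == "uri":
        return f"https://example.org/x{rng.randint(0, 10**6)}"
    if base == "uriorcurie":
        return f"samp:{rng.randint(0, 10**6):07d}"
    if base == "date":
        return f"20{rng.randint(10, 29)}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"
    if base == "datetime":
        return f"20{rng.randint(10, 29)}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}T12:00:00"
    return "v" + str(rng.randint(0, 10**6))


def random_documents(
    ms: MaterializedSchema,
    class_name: str,
    n: int,
    rng: random.Random,
    _depth: int = 0,
) -> list[InstanceDocument]:
    """Generate *n* schema-conformant documents of *class_name*.

    Required slots are always populated; optional ones with probability
    0.7; multivalued slots get 0-3 items (at least one when required).
    Class-ranged slots recurse (bounded depth).
    """
    docs = []
    for _ in range(n):
        values: dict[str, Any] = {}
        for slot in ms.induced[class_name]:
            if not slot.required and (rng.random() > 0.7 or _depth > 2):
                continue
            rng_name = ms.effective_range(slot)
            if ms.range_kind(rng_name) == "class" and _depth > 2:
                continue
            if slot.multivalued:
                count = rng.randint(1 if slot.required else 0, 3)
                values[slot.name] = [
                    _random_value(ms, rng_name, rng, _depth)
                    for _ in range(count)
                ]
            else:
                values[slot.name] = _random_value(ms, rng_name, rng, _depth)
        docs.append(InstanceDocument(class_name=class_name, values=values))
    return docs


def corrupt_document(
    ms: MaterializedSchema,
    doc: InstanceDocument,
    rng: random.Random,
) -> tuple[InstanceDocument, str]:
    """Inject exactly one schema violation into a copy of *doc*.

    The corruption is drawn from kinds both the native validator and a
    generated JSON Schema can detect (missing required slot, wrong scalar
    type, non-permissible enum value, list-shape violation), so the two
    validation routes must agree on the result.
    """
    import copy as _copy

    out = _copy.deepcopy(doc)
    slots = ms.induced[doc.class_name]
    candidates: list[tuple[str, str]] = []
    for slot in slots:
        rng_name = ms.effective_range(slot)
        kind = ms.range_kind(rng_name)
        if slot.required and slot.name in out.values:
            candidates.append((slot.name, "drop_required"))
        if slot.name in out.values and kind != "class":
            candidates.append((slot.name, "shape"))
            if kind == "enum":
                candidates.append((slot.name, "enum"))
            elif ms.range_base(rng_name) in (
                "integer", "float", "boolean", "string",
            ):
                candidates.append((slot.name, "type"))
    name, kind = candidates[rng.randrange(len(candidates))]
    slot = next(s for s in slots if s.name == name)
    if kind == "drop_required":
        del out.values[name]
    elif kind == "shape":
        value = out.values[name]
        out.values[name] = value[0] if isinstance(value, list) and value \
            else [value] if not isinstance(value, list) else "scalar"
    elif kind == "enum":
        out.values[name] = "__not_a_permissible_value__"
    else:  # type
        base = ms.range_base(ms.effective_range(slot))
        bad = 12345 if base == "string" else "not-a-number"
        if slot.multivalued:
            out.values[name] = [bad]
        else:
            out.values[name] = bad
    return out, f"{kind}:{name}"
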