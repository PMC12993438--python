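"""Best-practice checks for schemas.

The modeling language is permissive about style; the linter promotes
consistency: clear descriptions everywhere, CamelCase class names,
snake_case slot names, explicit slot ranges, and non-empty enumerations.
Rules are individually configurable (enabled flag, severity, parameters)
and linting is a pure function of the schema — it never mutates it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import yaml

from .errors import UnknownRuleId
from .schema_io import SchemaDefinition

__all__ = [
    "LintRuleConfig",
    "LintFinding",
    "LintReport",
    "lint_schema",
    "RULES",
]

CLASS_NAME_PATTERN = r"^[A-Z][A-Za-z0-9]*$"
SLOT_NAME_PATTERN = r"^[a-z][a-z0-9_]*$"

SEVERITIES = ("ERROR", "WARNING", "INFO")


@dataclass(frozen=True)
class LintFinding:
    rule: str
    element: str
    severity: str
    message: str


@dataclass
class LintReport:
    findings: list[LintFinding] = field(default_factory=list)

    @property
    def errors(self) -> int:
        return sum(1 for f in self.findings if f.severity == "ERROR")

    def to_text(self) -> str:
        if not self.findings:
            return "lint: clean\n"
        lines = [
            f"{f.severity} [{f.rule}] {f.element}: {f.message}"
            for f in self.findings
        ]
        return "\n".join(lines) + f"\n{len(self.findings)} finding(s)\n"

    def to_json_obj(self) -> dict:
        return {
            "findings": [
                {
                    "rule": f.rule,
                    "element": f.element,
                    "severity": f.severity,
                    "message": f.message,
                }
                for f in self.findings
            ]
        }


def _iter_slots(schema: SchemaDefinition):
    """(qualified-name, slot) over schema slots and class attributes."""
    for name, slot in schema.slots.items():
        yield name, slot
    for cname, cls in schema.classes.items():
        for name, slot in cls.attributes.items():
            yield f"{cname}.{name}", slot


def _rule_no_description(schema: SchemaDefinition, params: dict):
    for cname, cls in schema.classes.items():
        if not cls.description:
            yield cname, "class lacks a description"
    for qname, slot in _iter_slots(schema):
        if not slot.description:
            yield qname, "slot lacks a description"
    for ename, enum in schema.enums.items():
        if not enum.description:
            yield ename, "enum lacks a description"


def _rule_class_name_style(schema: SchemaDefinition, params: dict):
    pattern = params.get("pattern", CLASS_NAME_PATTERN)
    for cname in schema.classes:
        if not re.match(pattern, cname):
            yield cname, f"class name should be CamelCase ({pattern})"


def _rule_slot_name_style(schema: SchemaDefinition, params: dict):
    pattern = params.get("pattern", SLOT_NAME_PATTERN)
    for qname, slot in _iter_slots(schema):
        if not re.match(pattern, slot.name):
            yield qname, f"slot name should be snake_case ({pattern})"


def _rule_range_missing(schema: SchemaDefinition, params: dict):
    if schema.default_range:
        return
    for qname, slot in _iter_slots(schema):
        if slot.range is None:
            yield qname, "slot has no range and the schema has no default_range"


def _rule_enum_empty(schema: SchemaDefinition, params: dict):
    for ename, enum in schema.enums.items():
        if not enum.permissible_values:
            yield ename, "enum defines no permissible values"


RULES: dict[str, Callable[[SchemaDefinition, dict], Iterable[tuple[str, str]]]] = {
    "no_description": _rule_no_description,
    "class_name_style": _rule_class_name_style,
    "slot_name_style": _rule_slot_name_style,
    "range_missing": _rule_range_missing,
    "enum_empty": _rule_enum_empty,
}


@dataclass
class LintRuleConfig:
    """Per-rule settings keyed by registered rule id.

    ``rules`` maps rule-id to ``{"enabled": bool, "severity": str,
    "params": {...}}``; omitted rules run with defaults (enabled,
    WARNING severity).
    """

    rules: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        for rule_id, settings in self.rules.items():
            if rule_id not in RULES:
                raise UnknownRuleId(
                    f"unknown lint rule {rule_id!r}; known: {sorted(RULES)}"
                )
            severity = settings.get("severity", "WARNING")
            if severity not in SEVERITIES:
                raise UnknownRuleId(
                    f"rule {rule_id!r}: severity must be one of {SEVERITIES}"
                )

    @classmethod
    def from_yaml(cls, text: str) -> "LintRuleConfig":
        doc = yaml.safe_load(text) or {}
        return cls(rules=doc.get("rules", doc))

    def enabled(self, rule_id: str) -> bool:
        return self.rules.get(rule_id, {}).get("enabled", True)

    def severity(self, rule_id: str) -> str:
        return self.rules.get(rule_id, {}).get("severity", "WARNING")

    def params(self, rule_id: str) -> dict:
        return self.rules.get(rule_id, {}).get("params", {})


def lint_schema(
    schema: SchemaDefinition,
    config: Optional[LintRuleConfig] = None,
) -> LintReport:
    """Run every enabled rule; findings sorted by (element, rule)."""
    config = config or LintRuleConfig()
    findings: list[LintFinding] = []
    for rule_id, rule in RULES.items():
        if not config.enabled(rule_id):
            continue
        severity = config.severity(rule_id)
        for element, message in rule(schema, config.params(rule_id)):
            findings.append(LintFinding(rule_id, element, severity, message))
    findings.sort(key=lambda f: (f.element, f.rule))
    return LintReport(findings=findings)
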