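"""Core metamodel primitives.

The schema language is built from four element categories (classes, slots,
types, enumerations). This module holds the machinery those elements share:
compact identifiers (CURIEs) with prefix-map expansion/contraction, the
cardinality micro-grammar used by tabular schema authoring, and semantic
mappings to external vocabularies.

A CURIE is ``prefix:local``. The prefix must match
``[A-Za-z][A-Za-z0-9_.-]*``; everything after the first colon is the local
part (local parts like ``0000009`` — digits only — are common in ontology
namespaces and are accepted).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional

from .errors import (
    MalformedCardinality,
    MalformedCurie,
    UnknownPrefix,
)

__all__ = [
    "PrefixMap",
    "Cardinality",
    "UNBOUNDED",
    "ElementKind",
    "Mapping",
    "MAPPING_PREDICATES",
    "expand_curie",
    "contract_uri",
    "parse_cardinality",
    "is_curie",
    "is_uri",
]

_PREFIX_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_.\-]*$")
_CURIE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9_.\-]*):(\S*)$")
_URI_RE = re.compile(r"^(https?|ftp|urn|file)://?\S+$|^urn:\S+$")


def is_uri(text: str) -> bool:
    """True when *text* looks like a full URI rather than a CURIE."""
    return "://" in text or text.startswith("urn:")


def is_curie(text: str) -> bool:
    """Syntactic CURIE check: registered prefixes are not consulted."""
    if is_uri(text):
        return False
    return _CURIE_RE.match(text) is not None


class PrefixMap:
    """Ordered prefix -> URI-base registry.

    Loadable from (and dumpable to) the plain mapping shape a schema's
    ``prefixes:`` YAML block uses.
    """

    def __init__(self, entries: Optional[dict[str, str]] = None):
        self._entries: dict[str, str] = {}
        for prefix, base in (entries or {}).items():
            self.bind(prefix, base)

    def bind(self, prefix: str, base: str) -> None:
        if not _PREFIX_RE.match(prefix):
            raise MalformedCurie(f"illegal prefix {prefix!r}")
        if not base:
            raise ValueError(f"prefix {prefix!r} bound to empty base")
        self._entries[prefix] = base

    def __contains__(self, prefix: str) -> bool:
        return prefix in self._entries

    def __getitem__(self, prefix: str) -> str:
        return self._entries[prefix]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other) -> bool:
        if isinstance(other, PrefixMap):
            return self._entries == other._entries
        return NotImplemented

    def __repr__(self) -> str:
        return f"PrefixMap({self._entries!r})"

    def items(self):
        return self._entries.items()

    def as_dict(self) -> dict[str, str]:
        return dict(self._entries)


def expand_curie(curie: str, prefixes: PrefixMap, strict: bool = True) -> str:
    """Expand ``prefix:local`` to a full URI.

    Full URIs pass through unchanged (idempotence). In strict mode an
    unregistered prefix raises :class:`UnknownPrefix`; in lax mode it warns
    and returns the CURIE unchanged.
    """
    if is_uri(curie):
        return curie
    m = _CURIE_RE.match(curie)
    if m is None:
        raise MalformedCurie(f"not a CURIE (missing or misplaced colon): {curie!r}")
    prefix, local = m.group(1), m.group(2)
    if prefix not in prefixes:
        if strict:
            raise UnknownPrefix(f"prefix {prefix!r} not registered")
        warnings.warn(f"unknown prefix {prefix!r}; passing CURIE through", stacklevel=2)
        return curie
    return prefixes[prefix] + local


def contract_uri(uri: str, prefixes: PrefixMap) -> tuple[str, bool]:
    """Contract a URI to a CURIE using the longest matching base.

    Total function: returns ``(curie, True)`` on a match, else the input
    unchanged with ``False``.
    """
    best_prefix = None
    best_base = ""
    for prefix, base in prefixes.items():
        if uri.startswith(base) and len(base) > len(best_base):
            best_prefix, best_base = prefix, base
    if best_prefix is None:
        return uri, False
    return f"{best_prefix}:{uri[len(best_base):]}", True


# --- cardinality --------------------------------------------------------------

class _Unbounded:
    """Sentinel for an unbounded maximum cardinality."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNBOUNDED"


UNBOUNDED = _Unbounded()

# Tabular schema sources occasionally carry typographic dots instead of the
# ASCII two-dot separator; both the two-dot leader and the ellipsis are
# normalised before parsing.
_DOT_GLYPHS = {"‥": "..", "…": ".."}
_CARD_RE = re.compile(r"^(\d+)(?:\.\.(\d+|\*))?$")


@dataclass(frozen=True)
class Cardinality:
    """(min, max) multiplicity; ``max`` is an int or the UNBOUNDED sentinel.

    The default when a source states nothing is (0, 1): optional, single
    valued.
    """

    min: int = 0
    max: object = 1  # int or UNBOUNDED

    def __post_init__(self):
        if self.min < 0:
            raise MalformedCardinality(f"negative minimum {self.min}")
        if self.max is not UNBOUNDED:
            if not isinstance(self.max, int) or self.max < 1:
                raise MalformedCardinality(f"illegal maximum {self.max!r}")
            if self.min > self.max:
                raise MalformedCardinality(
                    f"minimum {self.min} exceeds maximum {self.max}"
                )

    @property
    def unbounded(self) -> bool:
        return self.max is UNBOUNDED

    @property
    def required(self) -> bool:
        return self.min >= 1

    @property
    def multivalued(self) -> bool:
        return self.unbounded or self.max > 1

    def render(self) -> str:
        """Canonical token: ``n``, ``n..m`` or ``n..*``."""
        if not self.unbounded and self.min == self.max:
            return str(self.min)
        hi = "*" if self.unbounded else str(self.max)
        return f"{self.min}..{hi}"


def parse_cardinality(token: str) -> Cardinality:
    """Parse a multiplicity token: ``n``, ``n..m`` or ``n..*``.

    ``0..1`` means optional, ``1`` required, ``0..*`` zero or more. The
    two-dot leader and ellipsis glyphs are accepted as ``..``.
    """
    text = token.strip()
    for glyph, ascii_sep in _DOT_GLYPHS.items():
        text = text.replace(glyph, ascii_sep)
    if not text:
        raise MalformedCardinality("empty cardinality token")
    m = _CARD_RE.match(text)
    if m is None:
        raise MalformedCardinality(f"unparseable cardinality token {token!r}")
    lo = int(m.group(1))
    hi_text = m.group(2)
    if hi_text is None:
        if lo < 1:
            # bare "0" would mean a slot that can never hold a value
            raise MalformedCardinality(f"bare token {token!r} implies max 0")
        return Cardinality(lo, lo)
    if hi_text == "*":
        return Cardinality(lo, UNBOUNDED)
    return Cardinality(lo, int(hi_text))


class ElementKind(Enum):
    """The four core element categories of the schema language."""

    CLASS = "class"
    SLOT = "slot"
    TYPE = "type"
    ENUM = "enum"


MAPPING_PREDICATES = ("exact", "close", "broad", "narrow", "related")


@dataclass(frozen=True)
class Mapping:
    """Semantic correspondence between a schema element and an external term.

    ``predicate`` is the SKOS-style match strength; ``target`` is the CURIE
    of the external vocabulary term.
    """

    predicate: str
    target: str

    def __post_init__(self):
        if self.predicate not in MAPPING_PREDICATES:
            raise ValueError(
                f"mapping predicate must be one of {MAPPING_PREDICATES}, "
                f"got {self.predicate!r}"
            )
        if not (is_curie(self.target) or is_uri(self.target)):
            raise MalformedCurie(f"mapping target is not a CURIE/URI: {self.target!r}")
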