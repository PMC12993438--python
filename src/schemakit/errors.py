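"""Exception hierarchy.

Every error raised by schemakit derives from :class:`SchemaKitError` so
callers can catch the whole family. Data problems found during validation
are *never* exceptions — they land in a ValidationReport.
"""


class SchemaKitError(Exception):
    """Base class for all schemakit errors."""


# --- CURIE / prefix machinery -------------------------------------------------

class MalformedCurie(SchemaKitError):
    """String does not match the prefix:local CURIE grammar."""


class UnknownPrefix(SchemaKitError):
    """CURIE prefix not registered in the prefix map (strict mode)."""


# --- cardinality grammar ------------------------------------------------------

class MalformedCardinality(SchemaKitError):
    """Token outside the n / n..m / n..* grammar, or min > max."""


# --- schema parsing -----------------------------------------------------------

class SchemaParseError(SchemaKitError):
    """Schema document cannot be parsed into a SchemaDefinition."""


class MissingSchemaId(SchemaParseError):
    """Schema document lacks the mandatory ``id`` URI."""


class DuplicateElementName(SchemaParseError):
    """Two elements of the same category share a name."""


# --- imports ------------------------------------------------------------------

class UnresolvableImport(SchemaKitError):
    """The resolver cannot supply an imported schema."""


class ImportCycle(SchemaKitError):
    """Import graph contains a cycle."""


class PrefixConflict(SchemaKitError):
    """Same prefix bound to different URI bases during a merge."""


# --- compilation --------------------------------------------------------------

class UnknownClass(SchemaKitError):
    """Named class does not exist in the schema."""


class CycleDetected(SchemaKitError):
    """is_a / mixin graph contains a cycle."""


class UnknownSlotReference(SchemaKitError):
    """Class references a slot name with no definition anywhere."""


class ConflictingIdentifier(SchemaKitError):
    """A class induces more than one identifier slot."""


class IntegrityError(SchemaKitError):
    """Aggregated referential-integrity failures.

    ``problems`` lists every dangling reference found, not just the first.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "schema integrity check failed:\n  " + "\n  ".join(self.problems)
        )


# --- schemasheets -------------------------------------------------------------

class SheetError(SchemaKitError):
    """Base for tabular-schema conversion errors."""


class MissingDirectiveRow(SheetError):
    """Table lacks the '>'-prefixed directive row."""


class UnknownDirectiveToken(SheetError):
    """Directive row contains a token outside the supported vocabulary."""


class CardinalityRequiredConflict(SheetError):
    """Cardinality min >= 1 contradicts an explicit required=FALSE cell."""


class BlankElementName(SheetError):
    """Row has neither a class nor a slot name."""


class EmptyTable(SheetError):
    """Inference needs at least one data row."""


# --- linter -------------------------------------------------------------------

class UnknownRuleId(SchemaKitError):
    """Lint configuration names a rule that is not registered."""


# --- transformations ----------------------------------------------------------

class TransformError(SchemaKitError):
    """Base for declarative-transformation errors."""


class UnknownOperationKind(TransformError):
    """Transform spec names an operation kind outside the registry."""


class TransformReferenceError(TransformError):
    """Operation references an element missing at its point in the sequence."""

    def __init__(self, op_index, missing, message=None):
        self.op_index = op_index
        self.missing = missing
        super().__init__(
            message
            or f"operation #{op_index} references missing element {missing!r}"
        )


class SplitArityMismatch(TransformError):
    """Split produced the wrong number of parts for its targets."""

    def __init__(self, path, got, expected):
        self.path = path
        super().__init__(
            f"{path}: split produced {got} parts, expected {expected}"
        )


class CastError(TransformError):
    """A split/merge part cannot be cast to its target range."""

    def __init__(self, path, value, range_name):
        self.path = path
        super().__init__(f"{path}: cannot cast {value!r} to {range_name}")
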