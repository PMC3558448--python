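"""Exception hierarchy.

Every domain error raised by the framework derives from :class:`MobyKitError`
so callers (and the CLI) can catch one base class.  Warning categories for
lossy format conversions live here as well.
"""

from __future__ import annotations


class MobyKitError(Exception):
    """Base class for all framework errors."""


# ---- registry / module framework -------------------------------------------

class NotFound(MobyKitError):
    """The requested resource id does not exist in the addressed module."""


class DuplicateName(MobyKitError):
    """A record with the same identity already exists."""


class EmptyName(MobyKitError):
    """A record name must be non-empty."""


class UnresolvedReference(MobyKitError):
    """A reference (category, datatype, namespace, tool, ...) does not resolve."""


class BadKind(MobyKitError):
    """Value outside a closed enumeration (parameter kind, cardinality, ...)."""


class DependencyExists(MobyKitError):
    """Non-cascading delete rejected because dependent records exist."""

    def __init__(self, message: str, dependents: tuple[str, ...] = ()):
        super().__init__(message)
        self.dependents = tuple(dependents)


class ImmutableField(MobyKitError):
    """Attempt to change a field that identifies the record (its id)."""


class UnknownField(MobyKitError):
    """Update names a field the record type does not declare."""


class UnknownLayer(MobyKitError):
    """attach_layer was given a layer name that is not registered."""


class UnknownBackend(MobyKitError):
    """Configuration references a backend name that is not registered."""


# ---- taxonomy ---------------------------------------------------------------

class CycleError(MobyKitError):
    """An IS/parent edge would create (or has created) a cycle."""


class ValidationError(MobyKitError):
    """A taxonomy-level invariant is violated (shadowed attribute, bad primitive)."""


# ---- composition ------------------------------------------------------------

class NoPath(MobyKitError):
    """No type-compatible operation chain exists within the depth bound."""


# ---- data engine ------------------------------------------------------------

class EmptyInput(MobyKitError):
    """Format detection requires non-empty content."""


class NoFormatter(MobyKitError):
    """No registered formatter covers the requested (format, datatype) pair."""


class ParseError(MobyKitError):
    """Content could not be parsed in the stated format."""


class LoaderFailure(MobyKitError):
    """A loader transform raised; carries the loader name and the cause."""

    def __init__(self, loader: str, cause: BaseException):
        super().__init__(f"loader {loader!r} failed: {cause}")
        self.loader = loader
        self.cause = cause


class MissingAttribute(MobyKitError):
    """Serialization requires an attribute the data does not carry."""


class BadPath(MobyKitError):
    """A structured-data path segment is not declared by the datatype."""


class TypeMismatch(MobyKitError):
    """Value type incompatible with the declared primitive/datatype."""


class ConversionError(MobyKitError):
    """A convert() stage failed; annotated with the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"conversion failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


class LossyFormatWarning(UserWarning):
    """Parsing/serializing discards information the source format carried."""


# ---- execution --------------------------------------------------------------

class NoWorker(MobyKitError):
    """No worker is registered for the location's protocol."""


class DuplicateProtocol(MobyKitError):
    """A worker for this protocol tag is already registered."""


class NoLocation(MobyKitError):
    """The tool has no location with a registered worker."""


class MissingInput(MobyKitError):
    """A mandatory input parameter was not supplied."""


class NotFinished(MobyKitError):
    """Results requested before the task reached SUCCEEDED."""

    def __init__(self, message: str, error: dict | None = None):
        super().__init__(message)
        self.error = error


class IllegalTransition(MobyKitError):
    """Internal guard: task status machine admits no such transition."""


class StageFailed(MobyKitError):
    """Pipeline enactment aborted at a stage (1-based index)."""

    def __init__(self, stage: int, cause: BaseException | str):
        super().__init__(f"pipeline stage {stage} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---- store / fixtures -------------------------------------------------------

class SchemaError(MobyKitError):
    """Registry store document is malformed or has an unsupported version."""


class IntegrityError(SchemaError):
    """Loaded store fails taxonomy validation or the referential scan."""


class BadSpec(MobyKitError):
    """Synthetic fixture specification out of bounds."""
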