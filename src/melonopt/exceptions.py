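"""Exception hierarchy used across the package."""


class MelonoptError(Exception):
    """Base class for all package errors."""


class SchemaError(MelonoptError):
    """A table is missing required columns or has unusable headers."""


class ValidationError(MelonoptError):
    """A value violates a domain invariant (row/field context in message)."""


class DomainError(MelonoptError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class FixtureLookupError(MelonoptError, KeyError):
    """Requested packaged fixture does not exist."""
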