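"""Exception and warning types shared across the package."""


class TxRestoreError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TxRestoreError):
    """A file could not be parsed (malformed line, non-numeric cell, ...)."""


class DuplicateIdError(ParseError):
    """An identifier column contains duplicates."""


class MissingValueError(ParseError):
    """An expression cell is missing (NA/empty); values must be complete."""


class DesignError(TxRestoreError):
    """The sample sheet / study design violates an invariant."""


class ConfigError(TxRestoreError):
    """A configuration field is invalid."""


class ZeroVarianceWarning(UserWarning):
    """A gene had zero pooled variance in ordinary-t mode; moderated fallback used."""


class EmptyAnnotationWarning(UserWarning):
    """No gene set survived intersection with the universe."""
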