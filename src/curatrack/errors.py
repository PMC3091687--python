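"""Exception hierarchy.

Everything raised on purpose derives from :class:`CuratrackError` so callers
(and the CLI) can catch tool errors without swallowing programming mistakes.
"""


class CuratrackError(Exception):
    """Base class for all errors raised by curatrack."""


class InvariantError(CuratrackError):
    """A data-model invariant was violated (bad interval, containment, ...)."""


class HierarchyError(CuratrackError):
    """Parent/child relationship is missing, cyclic or of the wrong level."""


class QueryError(CuratrackError):
    """Malformed entity query."""


class ParseError(CuratrackError):
    """Unreadable input file; carries a line number where available."""

    def __init__(self, message, line_number=None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class VerificationError(CuratrackError):
    """A document failed strict-schema verification; lists the violations."""

    def __init__(self, message, violations=()):
        super().__init__(message)
        self.violations = list(violations)


class ConfigError(CuratrackError):
    """Bad or missing source/rule configuration."""


class VocabularyError(CuratrackError):
    """Resolution term unknown or not applicable to the flag's category."""

    def __init__(self, message, applicable=()):
        super().__init__(message)
        self.applicable = list(applicable)


class StateError(CuratrackError):
    """Illegal flag state transition (e.g. resolving a resolved flag)."""


class EntityNotFoundError(CuratrackError):
    """Lookup of an entity id that is not in the store."""


class GenerationError(CuratrackError):
    """The synthetic-data generator was given an infeasible specification."""


class FormatError(CuratrackError):
    """Unsupported export format."""
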