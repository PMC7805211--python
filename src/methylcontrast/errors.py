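"""Exception hierarchy.

Exit-code mapping at the CLI boundary: UsageError -> 2, DataError and
ConfigurationError -> 1.
"""


class MethylContrastError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MethylContrastError):
    """A configuration value is outside its documented domain."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class UsageError(MethylContrastError):
    """An operation was invoked with arguments violating its contract."""


class DataError(MethylContrastError):
    """Input data violates a precondition (missing probe, empty cohort, ...)."""
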