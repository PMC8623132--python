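"""Exception hierarchy for decorpkin.

All package errors derive from :class:`DecorpkinError` so callers can catch
one base class at pipeline level while tests assert the specific subclass.
"""


class DecorpkinError(Exception):
    """Base class for all decorpkin errors."""


class SchemaError(DecorpkinError):
    """A delimited-text table does not match its declared schema."""


class TableParseError(DecorpkinError):
    """A cell could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class DataValidationError(DecorpkinError):
    """A domain-type invariant is violated (ordering, signs, lengths)."""


class WindowError(DecorpkinError):
    """A requested analysis window falls outside the observed times."""


class DegenerateDesignError(DecorpkinError):
    """A regression design is singular (e.g. all doses identical)."""


class DomainError(DecorpkinError):
    """A model was evaluated outside its mathematical domain."""


class RepeatedEigenvalueError(DomainError):
    """The compartmental rate matrix has a (numerically) repeated eigenvalue;
    the caller must use the confluent closed form instead of the macro set."""


class InconsistentMacroSetError(DomainError):
    """A macro (A, B, alpha, beta) set maps to a negative micro rate."""


class UndefinedRSquaredError(DecorpkinError):
    """R-squared is undefined because the observations have zero variance."""


class FitError(DecorpkinError):
    """A least-squares fit failed; carries best-so-far diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigError(DecorpkinError):
    """A run configuration is invalid (unknown model id, bad window, ...)."""
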