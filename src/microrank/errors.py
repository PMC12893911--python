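"""Exception hierarchy shared across the package."""


class MicrorankError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MicrorankError):
    """A file does not follow the expected dialect (header, columns)."""


class ValidationError(MicrorankError):
    """Input values violate a documented precondition or invariant."""


class InsufficientDataError(MicrorankError):
    """Too few complete observations for the requested statistic."""


class UndefinedCorrelationError(MicrorankError):
    """A correlation is undefined (constant vector after deletion)."""


class CollinearityError(MicrorankError):
    """A regression design matrix is singular."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column
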