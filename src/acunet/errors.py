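"""Exception hierarchy shared by all acunet modules.

``ValidationError`` and its relatives map to CLI exit code 2,
``NumericalError`` to exit code 3.
"""


class AcunetError(Exception):
    """Base class for all errors raised by acunet."""


class FormatError(AcunetError):
    """An input file does not have the expected structure (columns, header)."""


class ValidationError(AcunetError):
    """Input data violates a documented precondition."""


class UnknownAcupointError(ValidationError):
    """A free-text token could not be mapped to a standard acupoint code."""

    def __init__(self, token: str, message: str | None = None):
        self.token = token
        super().__init__(message or f"unknown acupoint token: {token!r}")


class DegenerateCaseError(ValidationError):
    """A case's data is degenerate for the requested statistic.

    Examples: a case with zero total count over the top-K acupoints, or a
    case whose selection probabilities are all equal (zero standard
    deviation, so z-scores are undefined).
    """

    def __init__(self, case_id: str, message: str):
        self.case_id = case_id
        super().__init__(f"case {case_id!r}: {message}")


class ParameterError(AcunetError):
    """A function argument is out of its documented range."""


class ConfigError(AcunetError):
    """A pipeline or generator configuration is invalid or incomplete."""


class NumericalError(AcunetError):
    """An iterative numerical routine failed to converge.

    Carries diagnostics so the caller can report iteration counts.
    """

    def __init__(self, message: str, *, iterations: int | None = None,
                 residual: float | None = None):
        self.iterations = iterations
        self.residual = residual
        if iterations is not None:
            message = f"{message} (iterations={iterations}, residual={residual})"
        super().__init__(message)
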