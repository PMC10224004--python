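"""Exception hierarchy.

Two broad families matter for the CLI exit-code contract: schema problems
(malformed input tables, exit code 2) and numerical/domain problems
(physically invalid values, exit code 3).
"""


class PartisolError(Exception):
    """Base class for all package errors."""


class SchemaError(PartisolError):
    """Malformed input table or configuration (missing column, bad cell).

    Carries enough context to name the offending row/column in messages.
    """

    exit_code = 2


class DomainError(PartisolError):
    """Physically or numerically invalid input to an analysis operation."""

    exit_code = 3


class InvalidCompositionError(DomainError):
    """Mole-fraction conversion left the open interval (0, 1)."""


class InsufficientDataError(DomainError):
    """Fewer points than the operation's minimum."""


class DegenerateDesignError(DomainError):
    """Regression design with no spread in the predictor."""


class NonSuppressedPointError(DomainError):
    """Distribution coefficient not strictly below its no-host baseline,
    so the log-linearization is undefined for that point."""
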