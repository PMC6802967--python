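"""Exception hierarchy shared across the pipeline.

Errors are split by who can fix them: ``ConfigurationError`` for bad
settings (column maps, thresholds, region definitions), ``ValidationError``
for inputs that violate a stated invariant, and ``DomainError`` for values
outside the mathematical domain of an operation.
"""


class TurnoverError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(TurnoverError):
    """A user-supplied configuration is inconsistent or incomplete."""


class ValidationError(TurnoverError):
    """An input record violates a structural invariant."""


class DomainError(TurnoverError, ValueError):
    """A value lies outside the mathematical domain of an operation."""
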