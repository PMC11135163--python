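"""Exception and warning types shared across the package."""


class DesviscError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DesviscError, ValueError):
    """A text input (sigma-profile file, CSV) could not be parsed."""


class ValidationError(DesviscError, ValueError):
    """An input violates a documented invariant."""


class SchemaError(DesviscError, ValueError):
    """A file does not match the expected column/field schema or version."""


class GenerationError(DesviscError, RuntimeError):
    """The synthetic generator was asked for a physically inconsistent sample."""


class ExtrapolationWarning(UserWarning):
    """A query feature lies outside the range seen during training.

    Predictions are still returned (the extrapolation workflow depends on
    them) but should be cross-checked against the applicability domain.
    """


class ConvergenceWarning(UserWarning):
    """Training stopped on its iteration budget rather than on tolerance."""
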