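"""Exception hierarchy.

All domain errors derive from :class:`SixmaError` so callers (and the CLI)
can catch one base class and turn it into a one-line diagnostic.
"""


class SixmaError(ValueError):
    """Base class for all domain errors raised by this package."""


class AlphabetError(SixmaError):
    """A sequence contains a character outside {A, C, G, T}."""


class LengthMismatchError(SixmaError):
    """Records in one dataset do not share a single window length."""


class EmptyClassError(SixmaError):
    """A class (positive or negative) has no records where one is required."""


class ParameterError(SixmaError):
    """An operation received a parameter outside its valid range."""


class NotFittedError(SixmaError):
    """A transform/predict was requested from an unfitted component."""


class FitError(SixmaError):
    """A fitting operation received data it cannot be fitted on."""


class DivergenceError(FitError):
    """Gradient-descent training produced a non-finite loss."""
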