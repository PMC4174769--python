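"""Exception hierarchy shared across the package."""


class SpiroquantError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SpiroquantError, ValueError):
    """A constructor or solver received a non-physical parameter."""


class DomainError(SpiroquantError, ValueError):
    """An argument fell outside the mathematical domain of an operation."""


class TrajectoryFormatError(SpiroquantError, ValueError):
    """A trajectory file does not follow the expected CSV layout."""


class EmptyTrajectoryError(SpiroquantError, ValueError):
    """Fewer than two valid pen samples remain after validation."""


class AlignmentError(SpiroquantError, ValueError):
    """The trajectory cannot be registered to the spiral template."""


class IncompleteDrawingError(SpiroquantError, ValueError):
    """The drawing does not cover enough of the template to quantify."""


class DegenerateInputError(SpiroquantError, ValueError):
    """Input is formally valid but statistically degenerate (zero variance,
    zero duration, non-positive value under a log transform, ...)."""


class CollinearityError(SpiroquantError, ValueError):
    """The regression design matrix is singular or nearly so."""
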