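"""Exception hierarchy.

Every contract violation raises a subclass of :class:`EndoquantError`, so
callers (and the CLI) can distinguish scientific-contract failures from
programming errors.
"""


class EndoquantError(ValueError):
    """Base class for all domain errors raised by this package."""


class InvalidParameterError(EndoquantError):
    """A physical parameter is outside its admissible range (e.g. K_D <= 0)."""


class FitDegenerateError(EndoquantError):
    """A titration series carries no information to fit (all responses equal)."""


class UndefinedAffinityError(EndoquantError):
    """Apparent affinity is undefined because the activated fraction is zero."""


class EmptyOverlapError(EndoquantError):
    """Two peak lists share no (residue, atom-group) keys."""


class WindowOverlapError(EndoquantError):
    """An integration window lies entirely outside a chromatogram's range."""


class NoComplexError(EndoquantError):
    """Measured complex concentration is zero or negative; K_D undefined."""


class SuperStoichiometricError(EndoquantError):
    """Complex concentration is >= a total concentration; mass balance violated."""


class UndefinedAbundanceError(EndoquantError):
    """Both gel bands are zero; relative abundance undefined."""


class UndefinedCoefficientError(EndoquantError):
    """A Mander's denominator is zero (no above-threshold signal)."""


class DegenerateThresholdError(EndoquantError):
    """Auto-thresholding on a constant image."""


class TableSchemaError(EndoquantError):
    """An input table is missing a required column or is empty."""


class TableParseError(EndoquantError):
    """A malformed value in an input file; message names file and line."""
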