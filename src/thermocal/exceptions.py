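"""Exception hierarchy for thermocal.

Every error raised deliberately by the package derives from
:class:`ThermocalError`, so callers (and the CLI) can catch one type.
"""


class ThermocalError(Exception):
    """Base class for all thermocal errors."""


class FormatError(ThermocalError):
    """A file does not follow the thermocal CSV dialect (malformed header,
    ragged rows, unparseable numbers)."""


class DatasetValidationError(ThermocalError):
    """A dataset violates a structural invariant (non-monotone axis,
    non-finite intensity, duplicate spectrum key, shape mismatch)."""


class ParameterError(ThermocalError):
    """An operation received an invalid parameter (even filter window,
    shape mismatch, bad range)."""


class RangeError(ThermocalError):
    """A spectral range selection retained no axis points."""


class AxisSpacingError(ThermocalError):
    """An operation requiring a uniformly spaced axis was given one that
    is not uniform within tolerance."""


class ConfigurationError(ThermocalError):
    """A simulator configuration is unusable (band outside axis support,
    no solute band, non-increasing hold temperatures)."""


class DesignError(ThermocalError):
    """The data do not realise the experimental design an operation needs
    (missing (concentration, temperature) cell, too few CV groups,
    missing isothermal slice)."""


class IdentifiabilityError(ThermocalError):
    """Too few distinct temperatures to identify the quadratic loading
    polynomials (at least three are required)."""


class RankError(ThermocalError):
    """Requested more factors/latent variables than the data support."""


class ConditioningError(ThermocalError):
    """A linear system is numerically singular (condition number above
    the 1e12 threshold)."""


class PipelineError(ThermocalError):
    """Chained models disagree about preprocessing state or axis."""


class CoverageError(ThermocalError):
    """A temperature-profile hold window contains no spectra."""


class AlignmentError(ThermocalError):
    """Two solubility curves do not share the same temperature grid."""


class DegenerateTargetError(ThermocalError):
    """The response is degenerate (zero-variance y, zero-mean predictions
    for which an RSD is undefined)."""
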