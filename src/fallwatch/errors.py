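"""Exception hierarchy for the fallwatch pipeline."""


class FallwatchError(Exception):
    """Base class for all fallwatch errors."""


class ConfigurationError(FallwatchError):
    """A configuration object violates its invariants."""


class MissingDataError(FallwatchError):
    """No valid sensor reading is available and no history exists."""


class ShortEventError(FallwatchError):
    """An event has too few raw points to be windowed."""


class DegenerateCovarianceError(FallwatchError):
    """Feature covariance is singular beyond what shrinkage can repair."""


class ParameterError(FallwatchError):
    """A model parameter is out of its valid range."""


class UndefinedPotentialError(FallwatchError):
    """The potential energy density is undefined (all points coincide
    with the query)."""


class FormatError(FallwatchError):
    """A file does not conform to its documented format contract."""
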