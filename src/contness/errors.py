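"""Exception hierarchy for contness.

All user-facing errors derive from :class:`ContnessError` so callers can
catch one base class at pipeline boundaries.
"""


class ContnessError(Exception):
    """Base class for all contness errors."""


class FormatError(ContnessError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ContnessError):
    """Parsed data violates an invariant (negative count, bad interval, ...)."""


class EssentialGeneError(ContnessError):
    """Raised when a model fit is requested for an all-zero (essential-candidate)
    gene; such genes are categorized by the count criteria, not modeled."""


class DegenerateDistributionError(ContnessError):
    """A coefficient distribution has no spread; empirical-null fitting is undefined."""


class TooFewValuesError(ContnessError):
    """Not enough finite coefficient values to estimate an empirical null."""


class ConfigError(ContnessError):
    """A run configuration is invalid or references missing inputs."""
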