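"""Exception hierarchy for the pipeline."""


class SilacMapError(Exception):
    """Base class for all package errors."""


class ConfigError(SilacMapError):
    """Invalid configuration value; the message names the offending field."""


class FormatError(SilacMapError):
    """A table does not conform to the expected dialect."""


class DataError(SilacMapError):
    """Physically impossible input values (e.g. negative intensities)."""


class StatisticError(SilacMapError):
    """The outlier statistic is undefined for the given input
    (empty/degenerate ratio distribution, too few quantified proteins)."""


class NormalizationError(SilacMapError):
    """A replicate has no usable ratios to center on."""
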