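"""Exception hierarchy shared by all stages.

Configuration problems (bad thresholds, impossible generator settings) and
data problems (malformed inputs, inconsistent identifiers) are kept distinct
so the command-line driver can map them to different exit codes.
"""


class RareGeneError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(RareGeneError):
    """A parameter or configuration value is outside its legal range."""

    exit_code = 2


class DataError(RareGeneError):
    """An input table or matrix violates the contract of an operation."""

    exit_code = 3


class ClassifierNotTrainableError(RareGeneError):
    """A per-cell noise classifier cannot be fit (training sets too small
    or degenerate)."""

    exit_code = 3
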