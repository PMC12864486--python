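"""Exception hierarchy shared across the pipeline.

Configuration problems and data problems are kept distinct so the CLI can map
them to different exit codes (2 and 3 respectively).
"""


class EegMciError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(EegMciError, ValueError):
    """A parameter or configuration value is out of its valid domain."""


class InvalidInputError(EegMciError, ValueError):
    """An input object violates a structural precondition."""


class InsufficientDataError(EegMciError, ValueError):
    """The input is structurally valid but too short/small for the operation."""


class DegenerateInputError(EegMciError, ValueError):
    """The input is degenerate for this statistic (e.g. constant series,
    all-zero band power) and the quantity is undefined."""


class UndefinedEntropyError(DegenerateInputError):
    """Sample entropy is undefined because no template matches were found."""
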