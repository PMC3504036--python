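"""Exception hierarchy shared across the package."""


class CleavescanError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CleavescanError, ValueError):
    """Malformed domain object or inconsistent arguments."""


class ParseError(CleavescanError, ValueError):
    """Malformed input file; message names file and line where possible."""


class OutOfAmpliconError(CleavescanError, ValueError):
    """A gene coordinate falls outside the templated span of an amplicon."""


class UnsupportedDivergenceError(CleavescanError, ValueError):
    """Sequence pair diverges beyond the supported alignment bounds."""


class UndefinedStatisticError(CleavescanError, ZeroDivisionError):
    """A ratio statistic whose denominator is empty."""


class SaturationError(CleavescanError, ValueError):
    """Evolutionary distance undefined (log argument non-positive)."""


class GenerationError(CleavescanError, RuntimeError):
    """Synthetic cohort generation could not satisfy the configuration."""
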