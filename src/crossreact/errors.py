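"""Exception hierarchy shared across the package."""


class CrossreactError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CrossreactError):
    """Invalid task, run, or simulation configuration."""


class FormatError(CrossreactError):
    """On-disk artifact does not match the documented schema."""


class ReferentialError(CrossreactError):
    """Cross-table reference (e.g. spike -> trial) cannot be resolved."""


class ValidationError(CrossreactError):
    """Table content violates an invariant (monotone event times, dense ids, ...)."""


class AnalysisError(CrossreactError):
    """An analysis precondition is not met (too few trials, zero variance, ...)."""
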