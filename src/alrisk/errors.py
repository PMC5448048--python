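"""Exception hierarchy shared across the pipeline."""


class AlriskError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AlriskError):
    """Invalid generator or analysis configuration (names the offending field)."""


class DataError(AlriskError):
    """Malformed cohort data (missing column, bad value, duplicate seq, ...)."""


class DomainError(AlriskError):
    """A value outside the supported domain (unknown category level, p not in [0,1], ...)."""


class FitError(AlriskError):
    """Model fitting failed (perfect separation, singular design, non-convergence)."""
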