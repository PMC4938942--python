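"""Exception hierarchy.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
EstimationError -> 4.
"""


class CsdecompError(Exception):
    """Base class for all package errors."""


class ConfigError(CsdecompError):
    """Invalid specification or analysis configuration."""


class DataError(CsdecompError):
    """Malformed, empty or schema-violating cohort data."""


class EstimationError(CsdecompError):
    """Model estimation failed (separation, collinearity, non-convergence)."""


class SeparationError(EstimationError):
    """A covariate perfectly partitions the outcome."""


class CollinearityError(EstimationError):
    """Rank-deficient design matrix."""
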