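"""Package exceptions with pipeline exit-code semantics."""


class PmddError(Exception):
    """Base class; exit code 1."""

    exit_code = 1


class ConfigError(PmddError):
    """Invalid configuration; exit code 2."""

    exit_code = 2


class DataError(PmddError):
    """Invalid or degenerate data; exit code 3."""

    exit_code = 3


class NotPositiveDefiniteError(ConfigError):
    """Implied liability covariance is not positive semi-definite."""


class SeparationError(DataError):
    """Perfect separation in a logistic fit."""


class CollinearityError(DataError):
    """Singular design matrix; names the offending columns."""
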