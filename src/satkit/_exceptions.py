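"""Exception and warning types shared across the package."""


class SatError(Exception):
    """Base class for all satkit errors."""


class FormatError(SatError, ValueError):
    """A file does not conform to the expected CSV dialect."""


class ValidationError(SatError, ValueError):
    """Data violate a structural invariant (monotonicity, finiteness, range)."""


class ConfigError(SatError, ValueError):
    """A configuration object carries inconsistent or non-positive values."""


class InsufficientDataError(SatError, ValueError):
    """Too few observations to carry out the requested computation."""


class NoKneeError(SatError, RuntimeError):
    """The learning-curve slope never falls below the cutoff fraction."""


class UndefinedCorrelationError(SatError, ValueError):
    """Pearson correlation requested on a zero-variance vector."""


class ValidationWarning(UserWarning):
    """Non-fatal data-quality finding (irregular sampling, rejected rows)."""
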