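"""Exception hierarchy shared across the package."""


class AgeselError(Exception):
    """Base class for all package errors."""


class ConfigError(AgeselError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(AgeselError):
    """A table is missing required columns, samples, or metadata."""


class ValidationError(AgeselError):
    """A table violates a domain invariant (e.g. poly_N > sites_N)."""


class UndefinedStatisticError(AgeselError):
    """A statistic is undefined for the given input (single age, all-zero tau vector, ...)."""


class DivergentMeanError(AgeselError):
    """The requested expectation does not exist (random walk not positive recurrent)."""


class NumericalError(AgeselError):
    """Quadrature or optimisation failed to reach the requested accuracy."""
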