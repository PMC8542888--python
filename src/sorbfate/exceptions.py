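"""Exception hierarchy shared across the package."""


class SorbfateError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SorbfateError):
    """A table is missing a mandatory column or has an unusable layout."""


class ParseError(SorbfateError):
    """A cell could not be converted to the expected type."""


class ValidationError(SorbfateError):
    """Values violate a physical or structural invariant."""


class UnitError(SorbfateError):
    """Inconsistent units within one data series."""


class ConfigError(SorbfateError):
    """Invalid filter/solver configuration."""


class StabilityError(SorbfateError):
    """Solver grid could not be refined to satisfy stability constraints."""


class FitError(SorbfateError):
    """A least-squares fit failed to converge or is otherwise unusable."""


class IdentifiabilityError(FitError):
    """The requested free parameters cannot be constrained by the data."""


class GenerationError(SorbfateError):
    """Synthetic-data generation hit an impossible parameter combination."""
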