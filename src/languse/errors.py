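"""Exception hierarchy shared across the package."""


class LanguseError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(LanguseError, ValueError):
    """An argument lies outside its mathematically valid range."""


class DomainError(LanguseError, ValueError):
    """An argument lies outside the model's domain (e.g. alpha >= alpha_star)."""


class EquilibriumDomainError(DomainError):
    """Payoffs violate the weighted-benefit condition, so the interior
    equilibrium would leave (0, 1)."""


class InsufficientDataError(LanguseError, ValueError):
    """Too few localities to fit the predictive model."""


class UnidentifiableError(LanguseError, ValueError):
    """The data carry no curve information (e.g. all alpha identical)."""


class BandUnreliableError(LanguseError, RuntimeError):
    """Too many bootstrap replicates failed to converge."""


class SchemaError(LanguseError, ValueError):
    """An input table does not match the canonical locality schema."""


class ConfigError(LanguseError, ValueError):
    """A pipeline or generator configuration is invalid."""
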