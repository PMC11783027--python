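"""Exception types shared across the package."""


class CohortLensError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CohortLensError):
    """An invalid configuration value (weights, probabilities, score tables)."""


class CatalogError(CohortLensError):
    """A condition or drug hierarchy violates its structural invariants."""


class UnknownItemError(CohortLensError, KeyError):
    """A name could not be resolved in a hierarchy or selection."""

    def __str__(self) -> str:  # KeyError would repr() the message
        return Exception.__str__(self)


class LevelError(CohortLensError):
    """A name was given at the wrong hierarchy level for the operation."""


class ReportError(CohortLensError):
    """A report specification cannot be rendered."""
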