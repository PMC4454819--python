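"""Exception types shared across the package."""


class EZMetricError(Exception):
    """Base class for all ezmetric errors."""


class SchemaError(EZMetricError):
    """An input table is missing a required column or names an unknown one."""


class ValidationError(EZMetricError):
    """A record violates a domain invariant (with row context when parsed from a file)."""


class FitError(EZMetricError):
    """Model fitting failed: rank deficiency or non-convergence."""
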