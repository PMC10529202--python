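"""Exception hierarchy.

Validation failures (bad schema, labels outside a declared scale) and
degenerate-distribution conditions (entropy of a constant variable) are kept
distinct so callers can mask undefined statistics without swallowing real
input errors.
"""


class OrdentError(Exception):
    """Base class for all package errors."""


class SchemaError(OrdentError):
    """A declared column, item or covariate is missing or malformed."""


class ValidationError(OrdentError):
    """Data values violate the declared ordinal scales."""


class DegenerateDistributionError(OrdentError):
    """A statistic is undefined because a margin is constant or empty."""
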