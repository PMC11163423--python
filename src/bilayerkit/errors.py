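"""Exception hierarchy for bilayerkit."""


class BilayerkitError(Exception):
    """Base class for all package errors."""


class ValidationError(BilayerkitError, ValueError):
    """A parameter or container field violates its contract.

    The message names the offending field.
    """


class AlignmentError(BilayerkitError, ValueError):
    """Traces that must share a time axis do not."""


class DegenerateReferenceError(BilayerkitError, ValueError):
    """A normalization denominator is zero or non-positive."""


class CoverageError(BilayerkitError, ValueError):
    """An isotherm does not reach the requested pressure range."""


class NoLiftOffError(BilayerkitError, ValueError):
    """Surface pressure never rises above the lift-off threshold."""


class SchemaError(BilayerkitError, ValueError):
    """A delimited table does not match the declared column schema."""
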