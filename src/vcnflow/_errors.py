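"""Exception hierarchy shared across the package."""


class VcnflowError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(VcnflowError, ValueError):
    """A numeric argument is outside its valid domain."""


class StructuralError(VcnflowError, ValueError):
    """Input data is malformed: missing channels, mismatched lengths, bad schema."""


class EstimationError(VcnflowError, ValueError):
    """A quantity cannot be estimated from the given data (e.g. censored reference Ct)."""
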