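"""Exception hierarchy for the ossishield package."""


class OssishieldError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(OssishieldError):
    """Infeasible cross-section geometry or out-of-range axial coordinate."""


class ConfigurationError(OssishieldError):
    """Unresolvable material name or invalid run configuration."""


class ParameterError(OssishieldError, ValueError):
    """A scalar parameter violates its physical bounds."""


class AggregationError(OssishieldError):
    """Empty, mixed or duplicated selection in a zone/site aggregation."""


class SamplingError(OssishieldError):
    """No surface element within tolerance of a requested gauge site."""


class FitError(OssishieldError):
    """Degenerate data passed to a regression (e.g. zero-variance abscissa)."""


class InputError(OssishieldError, ValueError):
    """Mismatched or malformed input arrays."""
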