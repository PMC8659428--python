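"""Exception hierarchy shared across the package."""


class ComtrackError(Exception):
    """Base class for all comtrack errors."""


class ValidationError(ComtrackError, ValueError):
    """Input data violates a stream- or type-level contract."""


class ConfigurationError(ComtrackError, ValueError):
    """Configuration objects are inconsistent or reference unknown entities."""


class DegenerateGeometryError(ComtrackError, ValueError):
    """Marker geometry is rank-deficient (collinear), so pose is not identifiable."""


class AlignmentError(ComtrackError, ValueError):
    """Two streams cannot be brought onto a common time base."""


class FilterError(ComtrackError, ValueError):
    """A smoothing filter cannot be applied to the given series."""


class SchemaError(ComtrackError, ValueError):
    """A manifest or table is missing required columns or contains invalid rows."""


class InsufficientDataError(ComtrackError, ValueError):
    """Too few complete observations for the requested statistical model."""
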