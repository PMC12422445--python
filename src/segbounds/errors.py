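"""Exception hierarchy shared across the pipeline."""


class SegboundsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SegboundsError):
    """An invalid parameter value (non-positive count, negative cost, ...)."""


class SchemaError(SegboundsError):
    """An input file or record violates the annotation schema."""


class DesignError(SegboundsError):
    """The experimental design is inconsistent (e.g. groups != conditions)."""


class EmptyProfileError(SegboundsError):
    """A boundary profile with zero total mass where mass is required."""


class GridMismatchError(SegboundsError):
    """Two profiles do not share a common discretization grid."""
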