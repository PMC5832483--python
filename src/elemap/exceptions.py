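"""Exception hierarchy for the LA-ICPMS image-reconstruction pipeline."""


class ElemapError(Exception):
    """Base class for all package errors."""


class FormatError(ElemapError):
    """A delimited TRA table does not match the declared dialect."""


class MonotonicityError(FormatError):
    """Timestamps are not strictly increasing."""


class SchemaError(ElemapError):
    """Series or table structure violates a contract (labels, column layout)."""


class StitchingError(ElemapError):
    """Multi-file concatenation produced an inconsistent time axis."""


class CoverageError(ElemapError):
    """The record is too short for the declared number of raster lines."""


class AdjustmentError(ElemapError):
    """A separation-point move would violate strict ordering."""


class BackgroundError(ElemapError):
    """A gas-blank window contains no usable readings."""


class GeometryError(ElemapError):
    """Grids or regions have incompatible shapes or degenerate geometry."""


class MaskedDataError(ElemapError):
    """An operation touched masked (invalid) cells, e.g. a masked corner."""


class RangeError(ElemapError):
    """A query point lies outside the grid's pixel-center bounding box."""


class QuantError(ElemapError):
    """Semi-quantification preconditions violated (missing element, bad RSF)."""


class ConfigError(ElemapError):
    """Run configuration is malformed or contains unknown keys."""
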