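"""Exception types shared across the pipeline."""


class CslimError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(CslimError, ValueError):
    """A parameter or data value violates its contract."""


class ShapeError(CslimError, ValueError):
    """Array dimensions are inconsistent with what an operation requires."""


class UnitsError(CslimError, ValueError):
    """A quantitative map carries the wrong units tag for an operation."""


class GridError(CslimError, ValueError):
    """Tile count or layout does not match the mosaic grid."""


class SampleSizeError(CslimError, ValueError):
    """Too few observations for a statistical fit."""


class DegenerateDataError(CslimError, ValueError):
    """Data carry no usable variation (all equal, zero variance, ...)."""


class FeasibilityError(CslimError, ValueError):
    """Requested phase/amplitude combination is unreachable by the forward model."""
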