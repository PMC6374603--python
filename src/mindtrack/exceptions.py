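"""Exception hierarchy used across the pipeline."""


class MindtrackError(Exception):
    """Base class for all package errors."""


class ParameterError(MindtrackError, ValueError):
    """A parameter value is outside its valid domain (e.g. non-positive timing)."""


class RangeError(MindtrackError, ValueError):
    """An event time or window falls outside the acquired time series."""


class DesignError(MindtrackError, ValueError):
    """A design matrix or cross-validation design is unusable (rank deficiency,
    single-class folds, degenerate splits)."""


class ShapeError(MindtrackError, ValueError):
    """Spatial grids or mask/weight shapes do not match."""


class DataError(MindtrackError, ValueError):
    """Input records are missing or non-finite where finite values are required."""


class InsufficientDataError(MindtrackError, ValueError):
    """Too few time points, subjects or values for the requested fit."""
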