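"""Exception hierarchy shared across the package."""


class DenVarError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DenVarError):
    """A required column is missing or malformed in an input table."""


class EmptyInputError(DenVarError):
    """No usable rows/cells remain after parsing or filtering."""


class DegenerateScaleError(DenVarError):
    """Marker is constant cohort-wide; min-max scaling is undefined."""


class DegenerateBandwidthError(DenVarError):
    """Sample spread is zero; Silverman's rule yields no bandwidth."""


class GridMismatchError(DenVarError):
    """Two density estimates do not share the same evaluation grid."""


class InsufficientSubjectsError(DenVarError):
    """Fewer than two subjects available for a pairwise operation."""


class InfeasibleShiftError(DenVarError):
    """Requested Beta mode shift pushes the mode to or beyond 1."""


class CovarianceError(DenVarError):
    """Similarity matrix is not a usable covariance (non-PSD, wrong shape)."""


class DegenerateInputError(DenVarError):
    """Input has no variation to fit (e.g. all survival times identical)."""


class ParameterError(DenVarError):
    """An argument is outside its valid range (e.g. K > N clusters)."""
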