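"""Exception hierarchy shared across the pipeline."""


class VascmarkError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VascmarkError):
    """Invalid configuration or generator parameters; names the offending field."""


class DataError(VascmarkError):
    """Malformed or inconsistent input data (files, tables, masks)."""


class GeometryError(VascmarkError):
    """Degenerate or ill-ordered contour geometry."""


class ResolutionError(VascmarkError):
    """Too few samples to carry out a fit at the acquired resolution."""


class FitError(VascmarkError):
    """A model fit produced an unusable result (e.g. non-positive upslope)."""


class PropagationError(VascmarkError):
    """Non-positive transit time between sampling sites."""


class StatsError(VascmarkError):
    """Statistical operation cannot be computed (zero variance, rank deficiency)."""
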