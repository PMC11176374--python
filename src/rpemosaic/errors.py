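"""Exception hierarchy shared across the pipeline."""


class RpeMosaicError(Exception):
    """Base class for all package errors."""


class ParameterError(RpeMosaicError, ValueError):
    """A parameter violates its documented contract."""


class DegenerateGeometryError(RpeMosaicError):
    """Too few or collinear points for a Voronoi partition or transform fit."""


class ScalingError(RpeMosaicError):
    """Pixel-size equation produced a non-positive physical scale."""


class ValidationError(RpeMosaicError):
    """Input table or configuration failed validation.

    The message names the offending column or key.
    """
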