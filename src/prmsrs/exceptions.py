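"""Exception hierarchy for prmsrs.

All package errors derive from :class:`PrmError` so callers can catch one
base class; the CLI maps them to exit code 2 (user error).
"""


class PrmError(Exception):
    """Base class for all prmsrs errors."""


class SpectrumParseError(PrmError):
    """A reference/spectrum file could not be parsed; message names the line."""


class DimensionError(PrmError):
    """Array shapes or lengths are inconsistent (axis vs bands, image shapes)."""


class AxisError(PrmError):
    """A wavenumber axis is non-monotone or contains duplicates."""


class CoverageError(PrmError):
    """A spectrum does not overlap the requested interpolation grid."""


class DegenerateSpectrumError(PrmError):
    """A spectrum is constant or zero and cannot be normalized.

    Raised on the reference path; the pixel path converts this condition to
    a masked score instead.
    """


class GridMismatchError(PrmError):
    """Two spectra that must share an axis do not."""


class ConfigError(PrmError):
    """Invalid configuration value (empty library, bad shift grid, ...)."""
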