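"""Typed exceptions shared across the package."""


class PrioralignError(Exception):
    """Base class for all package errors."""


class UnsupportedGeometryError(PrioralignError):
    """A geometry is not polygonal (point, line, or unknown type)."""


class InvalidGeometryError(PrioralignError):
    """An operation received an invalid geometry; repair it first."""


class CoordinateFrameError(PrioralignError):
    """Two layers are in different planar frames and cannot be overlaid."""


class ScoreUndefinedError(PrioralignError):
    """The science influence score is undefined (region fully covered)."""


class ConfigError(PrioralignError):
    """A configuration value is missing, malformed, or inconsistent."""


class DataError(PrioralignError):
    """Input data cannot support the requested computation."""


class UnsupportedFormatError(PrioralignError):
    """A file format is not supported by the readers/writers."""
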