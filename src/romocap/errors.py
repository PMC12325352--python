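"""Exception hierarchy shared across the pipeline stages."""


class RomocapError(Exception):
    """Base class for all package errors."""


class SchemaError(RomocapError):
    """A required marker is missing or labels cannot be mapped."""


class FormatError(RomocapError):
    """A file could not be parsed in the declared dialect."""


class IntegrityError(RomocapError):
    """A table violates its uniqueness contract."""


class GapError(RomocapError):
    """A trajectory gap cannot be interpolated."""


class FilterError(RomocapError):
    """Filtering preconditions violated (residual gaps, bad cutoff)."""


class DegenerateGeometryError(RomocapError):
    """Landmarks are collinear/coincident; a frame or angle is undefined."""


class SegmentationError(RomocapError):
    """No repetitions could be detected on the primary angle curve."""


class PoolingError(RomocapError):
    """Too few repetitions survive the exclusion rule to pool."""


class ConfigError(RomocapError):
    """Pipeline configuration is invalid."""
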