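"""Exception hierarchy shared across the pipeline stages."""


class NeuroprintError(Exception):
    """Base class for all package errors."""


class FormatError(NeuroprintError):
    """Unreadable or inconsistent input file/series."""


class GeometryError(NeuroprintError):
    """Invalid spatial metadata or degenerate geometry."""


class ParameterError(NeuroprintError):
    """Out-of-range or inconsistent parameter values."""


class BoundsError(NeuroprintError):
    """Coordinates outside the voxel grid."""


class SeedConflictError(NeuroprintError):
    """A voxel claimed as both foreground and background for one structure."""


class IncompleteSeedError(NeuroprintError):
    """A structure lacks the foreground and/or background seeds it needs."""


class EmptyStructureError(NeuroprintError):
    """An operation on a label with no voxels."""


class ConfigurationError(NeuroprintError):
    """Invalid pipeline or priority configuration."""
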