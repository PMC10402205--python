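"""Exception hierarchy shared across the package."""


class PaulmError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(PaulmError, ValueError):
    """Invalid transducer geometry (e.g. aperture wider than the sphere)."""


class ArgumentError(PaulmError, ValueError):
    """A parameter violates an operation's preconditions."""


class SimulationError(PaulmError):
    """Forward simulation cannot proceed (zero range, missing spectrum, ...)."""


class ReconstructionError(PaulmError):
    """Beamforming failed (e.g. most delays fall outside the record window)."""


class CapacityError(PaulmError):
    """A sparse operator would exceed the configured memory cap."""


class AlignmentError(PaulmError, ValueError):
    """Volumes/grids that must be co-registered are not."""


class ConfigurationError(PaulmError):
    """Bad configuration (singular unmixing matrix, unknown config keys, ...)."""


class MeasurementError(PaulmError):
    """A measurement (FWHM, profile) is undefined on the given data."""


class PipelineError(PaulmError):
    """A pipeline stage cannot run (e.g. every frame rejected by motion gating)."""


class DependencyError(PipelineError):
    """A requested pipeline stage is missing an upstream artifact."""


class VersionError(PaulmError):
    """Container schema version mismatch or corrupted metadata."""
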