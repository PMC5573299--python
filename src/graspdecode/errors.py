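"""Exception types shared across the package."""


class GraspDecodeError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(GraspDecodeError, ValueError):
    """A configuration value is out of range or inconsistent."""


class DetectionError(GraspDecodeError):
    """A kinematic landmark could not be located in a trial."""


class OnsetNotFoundError(DetectionError):
    """No supra-threshold wrist-speed sample satisfied the dwell rule."""


class EndNotFoundError(DetectionError):
    """No qualifying aperture-velocity crossing after the closing minimum."""


class SchedulingError(GraspDecodeError):
    """An event schedule could not be fitted into the run duration."""


class SchemaError(GraspDecodeError, ValueError):
    """An input file does not match the expected on-disk schema."""


class PreprocessingError(GraspDecodeError):
    """A voxel time series degenerated during conditioning (e.g. zero variance)."""
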