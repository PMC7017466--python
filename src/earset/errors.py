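"""Exception hierarchy for the earset pipeline."""


class EarsetError(Exception):
    """Base class for all earset-specific failures."""


class SidecarError(EarsetError):
    """A volume sidecar is missing or lacks a required key."""


class PackingError(EarsetError):
    """A phantom seed could not be placed without unintended overlap."""


class ReconstructionError(EarsetError):
    """Projection data violates a reconstruction precondition."""


class SegmentationError(EarsetError):
    """Ear separation or seed segmentation failed a contract."""


class OrientationError(SegmentationError):
    """A seed region is too degenerate for principal-axis orientation."""


class CalibrationError(EarsetError):
    """Virtual-weight calibration received unusable input."""


class ConfigError(EarsetError):
    """A pipeline configuration value is missing, unknown or out of range."""
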