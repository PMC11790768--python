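"""Exception types shared across the pipeline stages."""


class RibfracError(Exception):
    """Base class for all package-specific errors."""


class BoundsError(RibfracError, ValueError):
    """A window, crop or coordinate falls outside the image it refers to."""


class PlacementError(RibfracError, ValueError):
    """Requested fracture motifs cannot be placed without overlap."""


class ConfigError(RibfracError, ValueError):
    """An invalid configuration value was supplied."""


class DataError(RibfracError, ValueError):
    """Inputs violate a data contract (empty, misaligned, wrong shape)."""


class StratificationError(RibfracError, ValueError):
    """A class cannot be represented on both sides of a split."""


class PipelineError(RibfracError, RuntimeError):
    """A pipeline stage is missing an upstream artifact or failed."""
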