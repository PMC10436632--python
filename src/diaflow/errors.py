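"""Exception hierarchy for the diaflow pipeline.

Every stage raises a subclass of :class:`DiaflowError` so callers (and the
CLI) can report which stage failed and what to do about it.
"""


class DiaflowError(Exception):
    """Base class for all diaflow errors."""


class InputError(DiaflowError):
    """Unreadable, malformed or insufficient input data."""


class ConfigError(DiaflowError):
    """Invalid or incomplete configuration."""


class SegmentationError(DiaflowError):
    """Diaphragm segmentation failed (e.g. no bright region found)."""


class ClusteringError(DiaflowError):
    """Seed-point density filtering rejected every point."""


class TrackingError(DiaflowError):
    """Optical-flow tracking lost every point before the final frame."""


class CycleError(DiaflowError):
    """Respiratory-cycle detection found no usable peak/trough pair."""
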