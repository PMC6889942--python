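"""Exception hierarchy for the redoxwound pipeline.

Every stage raises a subclass of :class:`RedoxWoundError`; the CLI maps these
to non-zero exit codes while letting genuinely unexpected errors propagate.
"""


class RedoxWoundError(Exception):
    """Base class for all pipeline errors."""


class ScheduleError(RedoxWoundError):
    """A subject/day combination outside the experimental timeline."""


class ManifestError(RedoxWoundError):
    """Missing, duplicated or inconsistent manifest entries."""


class FormatError(RedoxWoundError):
    """An image file whose layout or bit depth is unsupported."""


class CalibrationError(RedoxWoundError):
    """Invalid cuvette reference, flat field, or double calibration."""


class ContractError(RedoxWoundError):
    """An operation received data in the wrong processing state."""


class SegmentationError(RedoxWoundError):
    """Wound segmentation produced an empty or unusable mask."""


class MaskError(RedoxWoundError):
    """A mask is incompatible with the frame it is applied to."""


class MetricError(RedoxWoundError):
    """A redox metric could not be computed (e.g. no valid pixels)."""


class DesignError(RedoxWoundError):
    """A statistical design requirement (balance, group count) is violated."""
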