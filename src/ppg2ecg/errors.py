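"""Exception hierarchy for the reconstruction pipeline.

Each pipeline stage raises a stage-specific subclass of
:class:`Ppg2EcgError` so that callers (and the CLI) can report which
stage failed without string-matching messages.
"""


class Ppg2EcgError(Exception):
    """Base class for all package errors."""


class FormatError(Ppg2EcgError):
    """A record file does not have the expected columns/layout."""


class SamplingError(Ppg2EcgError):
    """The time grid of a record is non-uniform beyond tolerance."""


class SynchronizationError(Ppg2EcgError):
    """PPG and ECG channels disagree in length or sampling rate."""


class RangeError(Ppg2EcgError):
    """A requested time or index range is empty or out of bounds."""


class ParameterError(Ppg2EcgError):
    """An operation received an invalid parameter combination."""


class SegmentationError(Ppg2EcgError):
    """Peak detection or cycle pairing produced no usable cycles."""


class DegenerateCycleError(Ppg2EcgError):
    """A cycle is too short to resample or normalize."""


class RankError(Ppg2EcgError):
    """The unregularized normal equations are singular."""


class EvaluationError(Ppg2EcgError):
    """A score could not be computed from the available annotations."""
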