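"""Exception hierarchy for the ictonet pipeline."""


class IctonetError(Exception):
    """Base class for all ictonet errors."""


class InvalidParameterError(IctonetError, ValueError):
    """A parameter value is outside its admissible range."""


class InvalidInputError(IctonetError, ValueError):
    """An input object violates a structural precondition."""


class UpsamplingRefusedError(InvalidParameterError):
    """Requested sampling rate exceeds the recording's rate."""


class DegenerateSignalError(InvalidInputError):
    """A signal is constant (or otherwise degenerate) where variation is required."""


class UndefinedCorrelationError(DegenerateSignalError):
    """Correlation is undefined because at least one input has zero variance."""


class NoFixedPointError(InvalidParameterError):
    """The uncoupled theta node has no stable fixed point (excitability >= 0)."""


class GridExhaustedError(IctonetError):
    """No BNI* curve saturates within the scanned coupling grid; widen the scan."""


class CalibrationError(IctonetError):
    """The reference-coupling bisection could not bracket or reach the target."""


class InvalidResectionError(InvalidInputError):
    """The resected node set is not a strict subset of the network's nodes."""


class InsufficientDataError(InvalidInputError):
    """Too few observations for the requested statistical test."""


class DegenerateTableError(InvalidInputError):
    """A contingency table has a zero margin."""


class DegenerateTimecourseError(InvalidInputError):
    """A BNI timecourse cannot be normalized (maximum is zero) or lacks ictal values."""


class GenerationError(IctonetError):
    """Synthetic-data generation failed (e.g. unstable coupling operator)."""


class StageError(IctonetError):
    """Pipeline failure wrapped with the name of the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
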