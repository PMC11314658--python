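"""Exception hierarchy shared by every stage of the pipeline."""


class EegFnirsError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(EegFnirsError, ValueError):
    """A parameter violates a stated precondition."""


class DomainError(EegFnirsError, ValueError):
    """Input values outside the mathematical domain of an operation."""


class IllConditionedCoefficientsError(EegFnirsError, ValueError):
    """Extinction-coefficient matrix is singular or near-singular."""


class AliasingError(InvalidParameterError):
    """A requested frequency is at or above the Nyquist frequency."""


class EmptyEpochsError(EegFnirsError, ValueError):
    """No valid epochs could be extracted."""


class DegenerateInputError(EegFnirsError, ValueError):
    """Statistical input with zero variance or otherwise undefined result."""


class StageError(EegFnirsError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original!r}")
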