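"""Exception types shared across the pipeline."""


class AntshiftError(Exception):
    """Base class for all package-specific errors."""


class CongruenceError(AntshiftError):
    """Two grids that must share shape/extent/decade do not."""


class OutOfDomainError(AntshiftError):
    """A point or value falls outside the spatial domain of a grid."""


class UndefinedEstimateError(AntshiftError):
    """An estimator has no defined value (e.g. zero total abundance)."""


class InfeasibleDesignError(AntshiftError):
    """A sampling design cannot be satisfied by the landscape."""


class StageError(AntshiftError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
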