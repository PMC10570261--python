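"""Exception hierarchy shared across the pipeline.

All validation failures derive from :class:`CardiactError` so the CLI can
map them onto exit code 2, leaving unexpected failures (exit code 1) distinct.
"""


class CardiactError(Exception):
    """Base class for all user-input / validation errors raised by cardiact."""


class InvalidParameterError(CardiactError, ValueError):
    """A scalar parameter is outside its documented domain."""


class FormatError(CardiactError, ValueError):
    """A file or in-memory table violates its format contract."""


class InsufficientDataError(CardiactError, ValueError):
    """Not enough usable samples to perform the requested operation."""


class DegenerateInputError(CardiactError, ValueError):
    """Input is formally valid but the operation is undefined on it."""


class RangeError(CardiactError, ValueError):
    """A requested coordinate lies outside the sampled range."""


class InfeasibleBudgetError(CardiactError, ValueError):
    """Tissue fractions exceed the unit volume they must share."""


class PipelineStageError(CardiactError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
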