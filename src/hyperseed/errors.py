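"""Exception hierarchy shared across the toolkit."""


class HyperseedError(Exception):
    """Base class for all hyperseed errors."""


class EnviFormatError(HyperseedError, ValueError):
    """ENVI header is missing a required key or declares an unsupported value."""


class EnviIntegrityError(HyperseedError, ValueError):
    """ENVI binary size disagrees with the header declaration."""


class DimensionError(HyperseedError, ValueError):
    """Array shapes or band counts do not line up."""


class ParameterError(HyperseedError, ValueError):
    """A parameter is outside its admissible range."""


class CapacityError(HyperseedError, ValueError):
    """A request exceeds what the data can supply (ROI count, class size)."""


class SpectralRangeError(HyperseedError, ValueError):
    """A spectral crop would retain no bands."""


class DataError(HyperseedError, ValueError):
    """Input data violates a basic requirement (non-finite values, ...)."""


class LabelError(HyperseedError, ValueError):
    """Class labels are unusable (single class for a binary machine, ...)."""


class NumericalError(HyperseedError, ArithmeticError):
    """A linear solve failed; usually fixable with a larger regularization jitter."""


class DivergenceError(HyperseedError, ArithmeticError):
    """Iterative training produced non-finite loss."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class GenerationError(HyperseedError, ValueError):
    """A synthetic-data spec violates its own invariants."""


class StageError(HyperseedError, RuntimeError):
    """Pipeline stage failure; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
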