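"""Exception hierarchy for the copgait pipeline."""


class CopgaitError(Exception):
    """Base class for all copgait errors."""


class ParameterError(CopgaitError, ValueError):
    """An argument or configuration value violates its contract."""


class FormatError(CopgaitError, ValueError):
    """A CSV file does not match the expected schema or invariants."""


class SynchronizationError(CopgaitError, RuntimeError):
    """No usable synchronization peak was found in one of the streams."""


class EmptyDatasetError(CopgaitError, RuntimeError):
    """A windowing or prediction request produced no samples."""


class UndefinedCOPError(CopgaitError, ValueError):
    """Center of pressure is undefined (e.g. zero total load)."""


class DivergenceError(CopgaitError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training loss at epoch {epoch}")
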