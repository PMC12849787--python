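"""Exception taxonomy.

Everything derives from :class:`SeizformerError` so callers can catch the
package's failures with one clause; each error also subclasses the closest
builtin (ValueError / IOError) so idiomatic numpy-style handling keeps working.
"""


class SeizformerError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(SeizformerError, ValueError):
    """An invalid configuration value or combination (names the offending key)."""


class SimulationError(SeizformerError, ValueError):
    """The synthetic generator cannot satisfy the requested conditions."""


class RecordIOError(SeizformerError, IOError):
    """A recording file is missing, unreadable, or not in a supported format."""


class FormatError(SeizformerError, ValueError):
    """A file parsed but required metadata (e.g. sampling rate) is absent."""


class MontageError(SeizformerError, ValueError):
    """A requested channel label is not present in the record."""


class ParameterError(SeizformerError, ValueError):
    """A numeric parameter is outside its admissible range."""


class SegmentationError(SeizformerError, ValueError):
    """The record is too short for the requested window length."""


class BalancingError(SeizformerError, ValueError):
    """Class balancing requested but one class is absent."""


class ShapeError(SeizformerError, ValueError):
    """Mismatched array shapes or lengths."""


class DomainError(SeizformerError, ValueError):
    """A value outside its mathematical domain (e.g. |r| > 1)."""


class StratificationError(SeizformerError, ValueError):
    """Too few samples of a class to fill the requested number of folds."""


class TrainingDivergenceError(SeizformerError, RuntimeError):
    """The training loss became non-finite."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class AUCError(SeizformerError, ValueError):
    """ROC-AUC requested with only one class present."""


class GraphInvariantError(SeizformerError, ValueError):
    """A channel graph violates a structural invariant (e.g. empty neighborhood)."""
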