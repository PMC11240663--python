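"""Typed errors raised across the pipeline.

Readers and transforms either return a valid object or raise one of these;
they never hand back a silently invalid container.
"""


class BroilerAccError(Exception):
    """Base class for all package errors."""


# --- I/O ---------------------------------------------------------------
class EmptyInput(BroilerAccError):
    """File parsed but contains no data rows."""


class NonMonotonicTime(BroilerAccError):
    """Time column is not strictly increasing."""


class IrregularSampling(BroilerAccError):
    """Time steps deviate from the nominal period by more than 1 %."""


class MissingColumn(BroilerAccError):
    """A required header column is absent."""


class SchemaMismatch(BroilerAccError):
    """A feature table is missing canonical columns."""


class OverlappingIntervals(BroilerAccError):
    """Behaviour intervals overlap in time."""


class UnknownBehaviour(BroilerAccError):
    """Behaviour label outside the known set (strict mode only)."""


# --- signal / features -------------------------------------------------
class LengthMismatch(BroilerAccError):
    """Parallel series have different lengths."""


class TraceTooShort(BroilerAccError):
    """Trace shorter than the filter's padding requirement."""


class SeriesTooShort(BroilerAccError):
    """Window series shorter than a statistic's minimum length."""


# --- dataset / classify ------------------------------------------------
class StrainTooSmall(BroilerAccError):
    """A strain has too few birds to split."""


class EmptyCell(BroilerAccError):
    """A (strain, behaviour) cell has no training rows."""


class ConstantLabels(BroilerAccError):
    """Information gain needs at least two distinct labels."""


class SingleClassTraining(BroilerAccError):
    """Forest training needs at least two classes."""


class TooFewRows(BroilerAccError):
    """Cross-validation needs at least k rows."""


class UnknownClass(BroilerAccError):
    """A label outside {sit, stand, walk} reached evaluation."""
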