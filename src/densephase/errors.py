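"""Exception hierarchy for densephase.

All package errors derive from :class:`DensePhaseError` so callers can
catch everything from one root; the leaves mirror the distinct failure
modes of the analysis contracts (bad input formats, degenerate series,
infeasible synthetic specs, non-convergent fits, ...).
"""


class DensePhaseError(Exception):
    """Base class for all densephase errors."""


class FormatError(DensePhaseError):
    """Structure/trajectory files disagree (atom counts, unreadable format)."""


class UnsupportedGeometryError(DensePhaseError):
    """Simulation box is not cubic within tolerance."""


class SamplingTooCoarseError(DensePhaseError):
    """Frame spacing too large to unwrap periodic coordinates unambiguously."""


class ArgumentError(DensePhaseError, ValueError):
    """Inconsistent argument shapes or values."""


class InsufficientFramesError(DensePhaseError):
    """A time-series analysis was asked of too few frames."""


class InfeasibleSpecError(DensePhaseError):
    """A synthetic-data spec cannot be realized (e.g. packing too dense)."""


class PlacementError(DensePhaseError):
    """Multi-copy box construction could not avoid steric clashes."""


class ResolutionError(DensePhaseError):
    """Series time step too coarse relative to the fastest relaxation time."""


class DegenerateSeriesError(DensePhaseError):
    """Zero-variance series where fluctuations are required."""


class AlphabetError(DensePhaseError):
    """Sequence contains letters outside the amino-acid alphabet."""


class InconsistentSequenceError(DensePhaseError):
    """Observed contact types are impossible given the sequence composition."""


class EmptyProfileError(DensePhaseError):
    """An all-zero interactivity profile cannot be normalized."""


class WindowError(DensePhaseError, ValueError):
    """Profile shorter than the requested smoothing window."""


class FitError(DensePhaseError):
    """A least-squares fit failed to converge or produced nonphysical values."""


class EstimationError(DensePhaseError):
    """All contributing estimates were rejected; nothing left to average."""


class NonphysicalFitError(FitError):
    """Fit succeeded numerically but violates physics (negative slope, ...)."""


class WrappedInputError(DensePhaseError):
    """MSD/unwrap received coordinates that still carry periodic jumps."""


class TopologyError(DensePhaseError):
    """Required atoms missing or molecular graph disconnected."""


class CompositionError(DensePhaseError):
    """System lacks a required component (e.g. no water for an RDF)."""


class DetectionError(DensePhaseError):
    """A data-driven boundary/feature could not be located."""


class UndersamplingError(DensePhaseError):
    """Too few samples for the requested histogram resolution."""


class IncompatibleSystemsError(DensePhaseError):
    """Entropy difference requested between unlike coordinate sets."""


class DomainError(DensePhaseError, ValueError):
    """Input outside the mathematical domain of a model formula."""


class GenerationError(DensePhaseError):
    """Stochastic geometric construction failed within its retry budget."""
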