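"""Exception hierarchy for the salamech pipeline."""


class SalamechError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(SalamechError):
    """A scenario or pipeline configuration value is out of its domain."""


class GridMismatchError(SalamechError):
    """Two rasters that must share geometry (shape, cell size, origin) do not."""


class RasterIOError(SalamechError):
    """A raster file could not be read or lacks georeferencing."""


class InsufficientMonthsError(SalamechError):
    """A climate stack does not contain the months an operation requires."""


class NoValidCellsError(SalamechError):
    """A sampling domain contains no usable (non-nodata, positive-weight) cells."""


class EmptyDomainError(SalamechError):
    """A spatial mask used to define a computation domain is empty."""


class UndefinedCorrelationError(SalamechError):
    """Rank correlation is undefined (zero rank variance or too few pairs)."""


class UndefinedCBIError(SalamechError):
    """The Continuous Boyce Index is undefined (e.g. constant suitability)."""


class EvaluationError(SalamechError):
    """A model evaluation was requested with an empty presence or background set."""


class InvalidFoldsError(SalamechError):
    """k-fold cross-validation requested with an unusable fold count."""


class NonConvergenceError(SalamechError):
    """An iterative fit failed to converge (e.g. separable data with no penalty)."""


class SingularFitError(SalamechError):
    """A regression design matrix is singular (e.g. constant elevations)."""


class PhysiologyDomainError(SalamechError):
    """A physiological model was evaluated outside its domain (e.g. mass <= 0)."""


class InvalidResolutionError(SalamechError):
    """Aggregation requested to a resolution finer than the source raster."""


class UnreachableError(SalamechError):
    """No least-cost route exists between two core areas."""

    def __init__(self, source: int, target: int):
        self.source = source
        self.target = target
        super().__init__(f"core {target} is unreachable from core {source}")


class InsufficientCoresError(SalamechError):
    """Fewer than two core areas are available for path modelling."""
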