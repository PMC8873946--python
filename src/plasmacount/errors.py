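"""Exception hierarchy shared across the pipeline."""


class PlasmaCountError(Exception):
    """Base class for all package-specific errors."""


class PlacementError(PlasmaCountError):
    """Rejection-sampling placement of synthetic objects failed."""


class BoundsError(PlasmaCountError):
    """A coordinate or region falls outside its parent frame."""


class DuplicateAnnotationError(PlasmaCountError):
    """Two point annotations share the same pixel."""


class PointFileParseError(PlasmaCountError):
    """A point TSV file could not be parsed.

    Carries the 1-based line number of the offending line.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ShapeError(PlasmaCountError):
    """An image shape violates a network or tiling constraint."""


class GeometryError(PlasmaCountError):
    """Mask/slide geometry mismatch."""


class ValidationError(PlasmaCountError):
    """Invalid value passed to an operation."""


class UndefinedPercentageError(PlasmaCountError):
    """Plasma-cell percentage requested with zero total cells."""


class TrainingError(PlasmaCountError):
    """Training aborted (e.g. non-finite loss)."""
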