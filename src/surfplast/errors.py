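"""Exception types shared across the package."""


class SurfplastError(Exception):
    """Base class for package errors."""


class PDBParseError(SurfplastError, ValueError):
    """An ATOM/HETATM record could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class StructureMismatchError(SurfplastError, ValueError):
    """Frames of a multi-model file disagree in atom count or identity."""


class SelectionError(SurfplastError, ValueError):
    """An atom selection matched nothing or is otherwise unusable."""


class GeometryError(SurfplastError, ValueError):
    """Degenerate geometry (collinear/rank-deficient points, bad grids)."""


class BoundaryError(SurfplastError, ValueError):
    """A position falls outside the grid it must be interpolated on."""


class CorrespondenceError(SurfplastError, ValueError):
    """Two structures cannot be matched atom-by-atom / residue-by-residue."""


class InsufficientFramesError(SurfplastError, ValueError):
    """An operation needs more frames than the ensemble provides."""
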