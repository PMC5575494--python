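"""Exception hierarchy.

Validation failures (bad ratings, malformed manifests) exit the CLI with
code 2; I/O problems with code 3.
"""


class Agree3DError(Exception):
    """Base class for all package errors."""


class MeshStructureError(Agree3DError, ValueError):
    """Mesh violates watertightness / orientation invariants."""

    def __init__(self, message: str, open_edges=None):
        super().__init__(message)
        self.open_edges = list(open_edges) if open_edges is not None else []


class MeshFormatError(Agree3DError, ValueError):
    """File could not be parsed as a valid PLY/STL mesh."""


class GridMismatchError(Agree3DError, ValueError):
    """Two voxel masks do not share origin/spacing/shape."""


class DegenerateResolutionError(Agree3DError, ValueError):
    """Voxelization produced an empty mask (spacing too coarse)."""


class GenerationError(Agree3DError, RuntimeError):
    """Synthetic shape generation or perturbation failed."""


class ValidationError(Agree3DError, ValueError):
    """Input table / manifest / config fails schema or range checks."""
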