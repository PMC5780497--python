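"""Exception hierarchy for flipdg."""


class FlipdgError(Exception):
    """Base class for all flipdg errors."""


class GeometryError(FlipdgError):
    """Invalid cell geometry (containment or topology violated)."""


class MeshQualityError(FlipdgError):
    """Mesh generation failed or produced degenerate elements."""


class ParameterError(FlipdgError):
    """Model or solver parameter outside its admissible range."""


class ScheduleError(FlipdgError):
    """Bleach schedule inconsistent with the solver time step."""


class AssemblyError(FlipdgError):
    """Finite element assembly failed (bad mesh or penalty parameter)."""


class SolverError(FlipdgError):
    """Linear solver failure during time stepping."""


class NormalizationError(FlipdgError):
    """Image intensities outside the normalized range [0, 1]."""


class FormatError(FlipdgError):
    """Unsupported image or mesh file format."""


class FieldMismatchError(FlipdgError):
    """Mesh and image raster do not cover each other."""
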