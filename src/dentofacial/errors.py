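"""Exception hierarchy for the dentofacial pipeline.

Every stage raises a subclass of :class:`DentofacialError` so that the
orchestrator and CLI can tag failures with the stage that produced them.
"""


class DentofacialError(Exception):
    """Base class for all package errors."""


class MeshFormatError(DentofacialError):
    """Unreadable, truncated or otherwise malformed mesh file."""


class EmptyMeshError(DentofacialError):
    """A mesh with no faces where geometry is required."""


class NotWatertightError(DentofacialError):
    """Operation requires a closed, consistently oriented mesh.

    Carries the offending open boundary edges in ``boundary_edges``.
    """

    def __init__(self, message, boundary_edges=None):
        super().__init__(message)
        self.boundary_edges = boundary_edges if boundary_edges is not None else []


class DomainError(DentofacialError, ValueError):
    """Parameter outside its mathematical domain (e.g. scale <= 0)."""


class EmptyInputError(DentofacialError, ValueError):
    """An empty sample or table where data is required."""


class DegenerateConfigurationError(DentofacialError):
    """Landmark configuration does not define a frame (e.g. collinear points)."""


class MissingLandmarkError(DentofacialError):
    """A landmark required by the selected alignment mode is absent."""


class InvalidSelectionError(DentofacialError):
    """Patch selection violates its invariants (disconnected, multi-loop...)."""


class ExtrusionError(DentofacialError):
    """Offsetting the patch produced a self-intersecting or degenerate solid."""


class ClosureError(DentofacialError):
    """Shell cannot be closed into a solid (multiple boundary loops...)."""


class SampleSizeError(DentofacialError, ValueError):
    """Statistical routine called with too few observations."""


class PairingError(DentofacialError, ValueError):
    """Paired samples have mismatched lengths."""


class DegenerateVarianceError(DentofacialError, ValueError):
    """Zero variance where a scale estimate is required."""


class SchemaError(DentofacialError, ValueError):
    """Cohort table violates the expected schema; message lists row numbers."""


class FeasibilityError(DentofacialError, ValueError):
    """Requested simulation configuration cannot be realised."""
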