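"""Exception hierarchy for nussplan.

Every error raised by the library derives from :class:`NussPlanError` so that
the CLI can catch one type and exit nonzero with a readable message.
"""


class NussPlanError(Exception):
    """Base class for all nussplan errors."""


class ParameterError(NussPlanError, ValueError):
    """An input parameter is outside its documented domain."""


class GeometryError(NussPlanError):
    """A geometric construction is degenerate or self-intersecting."""


class LandmarkError(NussPlanError):
    """Contour landmarks are missing, duplicated, or inconsistent."""


class TopologyError(NussPlanError):
    """A structural mesh is disconnected or otherwise ill-formed."""


class RigidBodyModeError(NussPlanError):
    """The constrained stiffness matrix is singular (an unconstrained mode)."""


class NoMatchError(NussPlanError):
    """No reference record satisfies the matching window."""


class InfeasibleDesignError(NussPlanError):
    """The requested bar cannot be realized as a convex curve."""


class CatalogueError(NussPlanError):
    """The required bar length exceeds the standard-size catalogue."""


class NoFeasiblePlanError(NussPlanError):
    """Every candidate operative plan fails the Haller or hypercorrection gate."""

    def __init__(self, message: str, failures: dict | None = None):
        super().__init__(message)
        #: map plan -> human-readable reason each candidate was rejected
        self.failures = failures or {}


class FormatError(NussPlanError):
    """A file does not conform to the expected on-disk format."""
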