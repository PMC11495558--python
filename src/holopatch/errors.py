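"""Exception hierarchy for holopatch.

All errors raised by the library derive from :class:`HoloPatchError` so
callers can catch one base class at pipeline boundaries (the CLI does).
"""


class HoloPatchError(Exception):
    """Base class for all holopatch errors."""


class MeshFormatError(HoloPatchError):
    """A mesh or point-cloud file could not be parsed under its format."""


class MeshContentError(HoloPatchError):
    """A file parsed but its content is unusable (e.g. an empty mesh)."""


class ParameterError(HoloPatchError, ValueError):
    """An argument violates a documented precondition."""


class BoundaryError(HoloPatchError):
    """A marked boundary is insufficient to define a patch circumference."""


class GeometryError(HoloPatchError):
    """Input geometry is degenerate for the requested operation."""


class ArtifactError(HoloPatchError):
    """The patch surface carries a self-intersection ('double fold') and the
    requested operation refuses to proceed on it."""

    def __init__(self, message, intersecting_pairs=None):
        super().__init__(message)
        self.intersecting_pairs = list(intersecting_pairs or [])
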