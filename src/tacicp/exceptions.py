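"""Exception hierarchy for tacicp.

All package errors derive from :class:`TacicpError` so callers can catch
everything with one clause while still distinguishing schema problems from
numerical degeneracies.
"""


class TacicpError(Exception):
    """Base class for all tacicp errors."""


class ValidationError(TacicpError):
    """A data-model invariant was violated (bad labels, empty set, ...)."""


class SchemaError(ValidationError):
    """An on-disk file does not conform to the interchange schema.

    The message names the offending record (slice / contour / row index).
    """


class DegenerateGeometryError(TacicpError):
    """Geometry too degenerate to process (zero-area polygon, collinear
    correspondences, coincident centroids, ...)."""


class UnmatchedLabelError(TacicpError):
    """A moving point has no fixed candidate with finite pair weight."""


class SingularSystemError(TacicpError):
    """The thin-plate-spline linear system is singular (coplanar or
    duplicated control points)."""
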