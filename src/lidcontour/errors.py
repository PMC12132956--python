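"""Exception hierarchy.

All package-specific failures derive from :class:`LidContourError` so callers
(and the CLI) can distinguish validation problems from genuine bugs.
"""


class LidContourError(Exception):
    """Base class for all lidcontour errors."""


class ValidationError(LidContourError, ValueError):
    """Malformed or inconsistent input data."""


class DomainError(ValidationError):
    """A numeric argument outside its mathematical domain (e.g. t not in [0, 1])."""


class CalibrationError(ValidationError):
    """Pixel-to-millimetre calibration impossible (coincident limbus points)."""


class OrientationError(ValidationError):
    """Landmarks inconsistent with the claimed eye orientation."""


class DegenerateGeometryError(ValidationError):
    """Geometry collapsed to a degenerate configuration (zero width, etc.)."""


class FeasibilityError(ValidationError):
    """A synthetic-eye specification with no realizable curve."""


class FitError(LidContourError):
    """Least-squares curve fit failed (rank deficiency, too few samples)."""


class InternalConsistencyError(LidContourError):
    """A cross-metric invariant was violated; indicates a bug, not bad input."""
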