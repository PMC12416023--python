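"""Exception hierarchy shared across the package.

All errors derive from :class:`ArmkinError` (a ``ValueError``) so callers can
catch package-level failures with one except clause while standard library
semantics are preserved.
"""


class ArmkinError(ValueError):
    """Base class for all armkin errors."""


class InvalidOrientationError(ArmkinError):
    """Quaternion or rotation matrix input is non-finite, zero-norm, or not a rotation."""


class ParameterError(ArmkinError):
    """A parameter is outside its documented domain."""


class InsufficientDataError(ArmkinError):
    """Too few samples/frames for the requested operation."""


class RankDeficiencyError(ArmkinError):
    """The input motion does not constrain the quantity being estimated."""


class UndefinedCorrelationError(ArmkinError):
    """Cross-correlation is undefined (zero-variance input)."""


class JointLimitError(ArmkinError):
    """A pose coordinate violates the model's joint limits."""


class MissingSegmentError(ArmkinError):
    """A required body segment is absent from the input series."""
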