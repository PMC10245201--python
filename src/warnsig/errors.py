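"""Exception hierarchy for the warnsig pipeline.

Every stage raises a subclass of :class:`WarnsigError` so callers can
distinguish pipeline failures from programming errors.
"""


class WarnsigError(Exception):
    """Base class for all warnsig errors."""


class ConfigurationError(WarnsigError):
    """Invalid or inconsistent study configuration."""


class ValidationError(WarnsigError):
    """A value violates a domain invariant (unknown class label, negative ms, ...)."""


class CalibrationError(WarnsigError):
    """Not enough reference patches to fit a colour correction."""


class DegeneratePatchError(CalibrationError):
    """Reference patches do not span colour space (singular design)."""


class NoPatternPixelsError(WarnsigError):
    """A region mask contains no non-black pattern pixels."""


class AlignmentError(WarnsigError):
    """Landmark configuration is degenerate; no affine warp can be fitted."""


class GeometryError(WarnsigError):
    """A transect leaves its region mask or other geometric precondition fails."""


class RenderError(WarnsigError):
    """A phenotype record cannot be rendered with the given geometry."""


class MissingDataError(WarnsigError):
    """An individual lacks a value for a characteristic (no imputation)."""


class ArityError(WarnsigError):
    """Wrong number of characteristic matrices passed to the fusion step."""


class LabelMismatchError(WarnsigError):
    """Characteristic matrices do not share identical individual labels."""


class InsufficientMembersError(WarnsigError):
    """A population has fewer members than the statistic requires."""


class MembershipError(WarnsigError):
    """A requested population or individual is not present in the study."""


class DegenerateDenominatorError(WarnsigError):
    """Mean allopatric centroid distance is zero; mimetic distance undefined."""


class InsufficientPointsError(WarnsigError):
    """Too few (Var, ms) points for a correlation test."""


class DegenerateDataError(WarnsigError):
    """Zero variance where a statistic needs spread."""


class UndefinedFractionError(WarnsigError):
    """Outlier fraction undefined: no conspecific alternative population."""
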