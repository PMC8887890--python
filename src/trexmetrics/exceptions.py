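"""Exception hierarchy for trexmetrics.

All domain-level failures derive from :class:`TrexError` so callers can
catch pipeline errors without masking programming errors.
"""


class TrexError(Exception):
    """Base class for all trexmetrics errors."""


class DomainError(TrexError, ValueError):
    """An input violates an operation's stated preconditions."""


class DegenerateInputError(DomainError):
    """Input is formally valid but geometrically/statistically degenerate
    (e.g. a constant image offered for histogram thresholding, or all
    landmarks coincident)."""


class NoRingError(DomainError):
    """A radial profile has no interior intensity maximum, so no ring
    radius can be fitted."""


class NoPairError(DomainError):
    """A line profile does not exhibit two resolvable peaks at the
    requested prominence (unresolved structure)."""


class UndefinedWidthError(DomainError):
    """FWHM is undefined because the profile peaks at its boundary or
    never crosses its half-maximum level."""


class PlacementError(TrexError, RuntimeError):
    """Rejection sampling could not place synthetic objects without
    overlap within the retry cap."""


class FormatError(TrexError, ValueError):
    """A file is readable but does not satisfy the format contract
    (e.g. an RGB TIFF offered as a grayscale image, missing calibration)."""
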