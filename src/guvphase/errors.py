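"""Exception hierarchy for guvphase.

Every operational failure raises a subclass of :class:`GuvPhaseError`, so
callers (and the CLI) can distinguish analysis failures from programming
errors.
"""


class GuvPhaseError(Exception):
    """Base class for all guvphase analysis errors."""


class ParameterError(GuvPhaseError, ValueError):
    """An input parameter is outside its documented domain."""


class GeometryError(ParameterError):
    """Requested geometry does not fit the image field or channel."""


class PackingError(GuvPhaseError):
    """Non-overlapping object placement failed within the retry budget."""


class NoForegroundError(GuvPhaseError):
    """Thresholding produced an empty mask (all-background image)."""


class EmptyMaskError(GuvPhaseError):
    """A region mask with no true pixels was supplied where one is required."""


class DivisionByZeroError(GuvPhaseError):
    """A ratio denominator (e.g. masked red-window sum) is zero."""


class UndefinedIndexError(GuvPhaseError):
    """Granulosity index undefined: filtered-image mean is non-positive."""


class DegenerateLabelsError(GuvPhaseError):
    """Phase-boundary fit requires at least one point of each state."""


class NoBleachError(GuvPhaseError):
    """FRAP normalization impossible: no intensity drop at the bleach frame."""


class FitFailureError(GuvPhaseError):
    """A nonlinear least-squares fit failed to converge."""


class NoPeakError(GuvPhaseError):
    """No second-derivative minimum found in the requested window."""


class NoSignalError(GuvPhaseError):
    """Zero integrated absorbance where a band area is required."""


class UnidentifiableError(GuvPhaseError):
    """Observed diffusion profiles carry no sizing information (flat)."""
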