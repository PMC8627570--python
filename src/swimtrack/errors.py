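"""Exception hierarchy.

Every failure mode that carries scientific meaning (no swimmer in the frame,
ambiguous head/tail, too few tail-beat cycles, ...) gets its own class so
callers can distinguish "bad input" from "bad parameters" without parsing
messages.
"""


class SwimtrackError(Exception):
    """Base class for all swimtrack errors."""


class ValidationError(SwimtrackError, ValueError):
    """Invalid parameter or argument value."""


class SamplingRateError(ValidationError):
    """Frame rate too low to resolve the body wave (Nyquist-style bound)."""


class FieldOfViewError(SwimtrackError):
    """Body leaves the requested image during rendering."""


class NoSwimmerError(SwimtrackError):
    """No foreground component of sufficient area in a frame."""


class AmbiguousCenterlineError(SwimtrackError):
    """Skeleton has no dominant elongated path (e.g. a disk-like mask)."""


class OrientationAmbiguousError(SwimtrackError):
    """Head and tail cannot be told apart by lateral-excursion variance."""


class InsufficientCyclesError(SwimtrackError):
    """Fewer tail-beat cycles available than the estimator requires."""


class NoOscillationError(SwimtrackError):
    """Lateral excursion is flat at the analysis station."""


class WaveNotResolvedError(SwimtrackError):
    """No wave extrema found along the body in any frame."""


class IncoherentWaveError(SwimtrackError):
    """Phase-versus-position fit too poor to define a wave speed."""


class NoNetTravelError(SwimtrackError):
    """Centroid track too short to define a heading / speed."""
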