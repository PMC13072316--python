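"""Exception hierarchy.

Every stage raises a distinct subclass so batch drivers can tally
rejection reasons (no quiet window, empty signal, no valid peak, ...)
without string matching.
"""


class AvirespError(Exception):
    """Base class for all package errors."""


class VideoFormatError(AvirespError):
    """Unreadable container, empty clip, or non-uniform frame sizes."""


class BoundsError(AvirespError):
    """Bounding box or frame range outside the clip."""


class AnnotationError(AvirespError):
    """Malformed or invariant-violating ROI annotation."""


class DetectionError(AvirespError):
    """Fallback detector found no usable body component."""


class ScreeningError(AvirespError):
    """Motion screening could not run (degenerate box, window too long)."""


class NoQuietSegmentError(ScreeningError):
    """No 10-s window satisfied the quiet-state amplitude threshold."""


class DecompositionError(AvirespError):
    """Steerable-pyramid construction failed (frame too small, bad levels)."""


class ConfigError(AvirespError):
    """Invalid pipeline or band-pass configuration."""


class EmptySignalError(AvirespError):
    """No pyramid pixel survived the amplitude floor; no motion signal."""


class NoValidPeakError(AvirespError):
    """No spectral peak inside the respiratory band passed validity checks."""


class EvaluationError(AvirespError):
    """Insufficient or invalid data for the requested metric."""
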