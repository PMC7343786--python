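"""Exception hierarchy for the plaquesync pipeline."""


class PlaqueSyncError(Exception):
    """Base class for all plaquesync errors."""


class InvalidModelError(PlaqueSyncError):
    """A motion model or phantom geometry violates its invariants."""


class GenerationError(PlaqueSyncError):
    """Synthetic data could not be generated (e.g. motion leaves the frame)."""


class CohortSpecError(PlaqueSyncError):
    """A cohort specification is degenerate (too few groups, negative sd...)."""


class TrackingError(PlaqueSyncError):
    """Block matching failed; message names the offending pixel and frame."""


class TooShortPlaqueError(PlaqueSyncError):
    """Plaque contour has too few pixels to survive edge trimming."""


class TooShortSeriesError(PlaqueSyncError):
    """Time series shorter than the filter warm-up / analysis window."""


class NoDominantFrequencyError(PlaqueSyncError):
    """No in-band periodogram peak rises above the noise floor."""


class DegenerateWaveformError(PlaqueSyncError):
    """A waveform required for pairing or selection is degenerate."""


class UndefinedCorrelationError(PlaqueSyncError):
    """Cross-correlation undefined (constant input, zero denominator)."""


class FeatureExtractionError(PlaqueSyncError):
    """No valid waveform pair for a cross-correlation type."""


class NormalisationError(PlaqueSyncError):
    """Grayscale normalisation impossible (equal reference medians)."""


class DegenerateRegionError(PlaqueSyncError):
    """Plaque region too small for echogenicity estimation."""
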