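"""Exception hierarchy for the analysis pipeline.

Every error raised by cardiomap derives from :class:`CardiomapError` so
batch drivers can isolate per-recording failures without masking bugs.
"""


class CardiomapError(Exception):
    """Base class for all cardiomap errors."""


class ParameterError(CardiomapError, ValueError):
    """An operation was called with an invalid parameter (e.g. filter
    cutoff at or above Nyquist, even box-filter size)."""


class InvalidShapeError(CardiomapError, ValueError):
    """A waveform shape violates its invariants (non-positive durations)."""


class InsufficientDurationError(CardiomapError, ValueError):
    """A simulated schedule yields too few beats for ten-beat analysis."""


class GeometryError(CardiomapError, ValueError):
    """ROI or chamber-mask geometry is out of bounds or overlapping."""


class FlatSignalError(CardiomapError, ValueError):
    """Peak-to-baseline excursion is below the flatness threshold; the
    trace cannot be normalized (e.g. an ROI placed on background)."""


class NoRhythmError(CardiomapError, ValueError):
    """Fewer than two beats detected; no rhythm to analyze."""


class OrderingError(CardiomapError, ValueError):
    """Event times are not monotonically increasing."""


class DegenerateBeatError(CardiomapError, ValueError):
    """A beat has no positive upstroke slope."""


class UnterminatedBeatError(CardiomapError, ValueError):
    """A beat never recovers to the 80% level inside its window."""


class InsufficientBeatsError(CardiomapError, ValueError):
    """Fewer complete beats than the protocol requires."""


class AlignmentError(CardiomapError, ValueError):
    """Signal averaging produced an empty alignment axis."""


class InsufficientDataError(CardiomapError, ValueError):
    """Too few activations to classify a conduction pattern."""


class NoConductionError(CardiomapError, ValueError):
    """No matched atrial-ventricular pairs."""


class StatisticsError(CardiomapError, ValueError):
    """Invalid input to a statistical summary or test."""


class IntegrityError(CardiomapError, ValueError):
    """Duplicate or inconsistent cohort records."""


class PresetLookupError(CardiomapError, KeyError):
    """Unknown cohort-preset label."""


class FormatError(CardiomapError, ValueError):
    """A file could not be read as a recording, or metadata is missing
    or inconsistent with the run configuration."""


class ConfigError(CardiomapError, ValueError):
    """Run configuration is invalid or incomplete."""
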