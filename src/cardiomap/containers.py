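"""Shared in-memory containers for recordings and per-beat results.

Conventions used throughout the package: time is handled in milliseconds
internally (seconds only in CSV time columns), sample indices are 0-based,
and beat windows are half-open ``[onset, end)`` intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import GeometryError, ParameterError

Chamber = Literal["atrium", "ventricle"]
Modality = Literal["Vm", "Ca"]
Polarity = Literal["positive", "negative"]


@dataclass
class Trace:
    """A uniformly sampled fluorescence time series from one chamber.

    Parameters
    ----------
    values : ndarray
        Fluorescence samples in arbitrary units.
    sample_rate : float
        Sampling rate in Hz.
    chamber, modality, polarity : str
        Chamber label (``atrium``/``ventricle``), signal modality
        (``Vm``/``Ca``) and polarity of the optical signal (``negative``
        means depolarization/Ca release moves fluorescence downward).
    """

    values: np.ndarray
    sample_rate: float
    chamber: Chamber = "atrium"
    modality: Modality = "Vm"
    polarity: Polarity = "positive"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ParameterError("a trace needs at least 2 samples")
        if not self.sample_rate > 0:
            raise ParameterError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def dt_ms(self) -> float:
        """Sample period in milliseconds."""
        return 1000.0 / self.sample_rate

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms

    def with_values(self, values: np.ndarray) -> "Trace":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class NormalizedTrace(Trace):
    """A per-beat normalized trace (dF_n): within each analyzed beat the
    baseline maps to 0 and the beat peak to 1.

    ``beat_refs`` stores the per-beat ``(baseline, peak)`` raw-intensity
    reference pairs used for scaling, one per beat window.
    """

    beat_refs: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class FrameStack:
    """A time x row x column intensity array (16-bit camera range).

    ``frame_rate`` is frames per second; ``modality`` tags whether the
    fluorescence reports membrane voltage or intracellular calcium.
    """

    intensities: np.ndarray
    frame_rate: float
    modality: Modality = "Vm"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or self.intensities.shape[0] < 2:
            raise ParameterError("frame stack must be (time, row, col) with >= 2 frames")
        if not self.frame_rate > 0:
            raise ParameterError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.intensities.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (int(self.intensities.shape[1]), int(self.intensities.shape[2]))


@dataclass(frozen=True)
class ROISpec:
    """A square pixel window whose mean intensity gives a chamber trace.

    ``window`` is the side length in pixels.  Odd windows are centered on
    ``center``; even windows (the adult protocol's literal 10 x 10 option)
    are anchored so ``center`` is the top-left of the central 2 x 2 block.
    """

    center: tuple[int, int]
    window: int = 5
    chamber: Chamber = "atrium"

    def bounds(self, frame_shape: tuple[int, int]) -> tuple[int, int, int, int]:
        """Return (r0, r1, c0, c1) half-open pixel bounds, validated
        against ``frame_shape``."""
        if self.window < 1:
            raise ParameterError("ROI window must be >= 1")
        half = self.window // 2
        r, c = self.center
        if self.window % 2:
            r0, c0 = r - half, c - half
        else:
            r0, c0 = r - half + 1, c - half + 1
        r1, c1 = r0 + self.window, c0 + self.window
        if r0 < 0 or c0 < 0 or r1 > frame_shape[0] or c1 > frame_shape[1]:
            raise GeometryError(
                f"ROI {self.window}x{self.window} at {self.center} exceeds "
                f"frame of shape {frame_shape}"
            )
        return r0, r1, c0, c1


@dataclass(frozen=True)
class BeatWindow:
    """One beat as sample indices: upstroke onset, peak, and half-open end."""

    onset: int
    peak: int
    end: int

    def __post_init__(self) -> None:
        if not (self.onset <= self.peak < self.end):
            raise ParameterError(
                f"beat window indices must satisfy onset <= peak < end, "
                f"got ({self.onset}, {self.peak}, {self.end})"
            )


@dataclass(frozen=True)
class Activation:
    """The activation point of one beat: the time and magnitude of the
    maximal normalized upstroke slope (dF_n/dt_max)."""

    time_ms: float
    slope: float  # dF_n/dt_max, 1/s
    peak_time_ms: float
    peak_value: float


@dataclass
class BeatFeatures:
    """Per-beat feature values and their mean +/- SEM over the selected
    beats.  ``duration80_ms`` is APD80 for Vm and CaTD80 for Ca."""

    modality: Modality
    chamber: Chamber
    hr_bpm: np.ndarray
    upstroke_speed: np.ndarray
    duration80_ms: np.ndarray
    summary: dict[str, tuple[float, float]] = field(default_factory=dict)

    def feature(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass
class AveragedWaveform:
    """The pointwise mean of beats aligned at their activation points.

    ``times_ms`` has t = 0 at the alignment point; ``n_beats`` is the
    number of beats contributing to the average.
    """

    times_ms: np.ndarray
    values: np.ndarray
    sample_rate: float
    n_beats: int
    chamber: Chamber = "atrium"
    modality: Modality = "Vm"
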