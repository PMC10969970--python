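"""Turn raw frame stacks or traces into filtered, normalized chamber traces.

The chain mirrors standard optical-mapping practice: a spatial box filter
on the frames, mean-intensity extraction over a small ROI per chamber, a
zero-phase temporal Butterworth low-pass, and per-beat normalization of
the fluorescence to dF_n (baseline 0, beat peak 1).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import butter, filtfilt

from .containers import BeatWindow, FrameStack, NormalizedTrace, ROISpec, Trace
from .errors import FlatSignalError, ParameterError


def temporal_lowpass(trace: Trace, cutoff: float = 50.0, order: int = 4) -> Trace:
    """Zero-phase Butterworth low-pass filter.

    Applied forward and backward (``filtfilt``) so activation times are
    not delayed; the effective magnitude response is the squared
    Butterworth response.  Length is preserved.
    """
    if not 0 < cutoff < trace.sample_rate / 2.0:
        raise ParameterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={trace.sample_rate / 2} Hz)"
        )
    if order < 1:
        raise ParameterError("filter order must be >= 1")
    b, a = butter(order, cutoff / (trace.sample_rate / 2.0))
    return trace.with_values(filtfilt(b, a, trace.values))


def spatial_boxfilter(stack: FrameStack, size: int = 5) -> FrameStack:
    """Convolve each frame with a uniform ``size`` x ``size`` kernel
    (reflect padding at the borders)."""
    if size % 2 == 0:
        raise ParameterError("box filter size must be odd")
    if size > min(stack.frame_shape):
        raise ParameterError("box filter larger than the frame")
    filtered = uniform_filter(
        stack.intensities.astype(float), size=(1, size, size), mode="reflect"
    )
    return FrameStack(filtered, stack.frame_rate, stack.modality)


def extract_roi_trace(stack: FrameStack, roi: ROISpec) -> Trace:
    """Per-frame mean intensity over the ROI window."""
    r0, r1, c0, c1 = roi.bounds(stack.frame_shape)
    values = stack.intensities[:, r0:r1, c0:c1].mean(axis=(1, 2))
    return Trace(values, stack.frame_rate, roi.chamber, stack.modality)


def apply_polarity(trace: Trace) -> Trace:
    """Invert a negative-polarity trace about its median so the upstroke
    points upward; positive-polarity traces pass through unchanged."""
    if trace.polarity == "positive":
        return trace
    med = float(np.median(trace.values))
    out = trace.with_values(2.0 * med - trace.values)
    out.polarity = "positive"
    return out


def noise_estimate(values: np.ndarray) -> float:
    """Robust noise sd from median absolute successive differences."""
    d = np.diff(np.asarray(values, dtype=float))
    return float(np.median(np.abs(d)) / (0.6745 * np.sqrt(2.0)))


def beat_baseline(
    values: np.ndarray,
    sample_rate: float,
    window: BeatWindow,
    prev_peak: int | None,
    amp_low: float,
    amp_high: float,
) -> float:
    """Median of the pre-upstroke rest segment of one beat.

    The rest segment is the low-lying portion (below 15 % of the robust
    amplitude) of the diastolic interval between the previous beat's peak
    and 5 ms before this beat's upstroke onset, restricted to its last
    30 %; the first beat uses the leading segment of the trace.
    """
    dt_ms = 1000.0 / sample_rate
    gap = max(1, int(round(5.0 / dt_ms)))
    hi = window.onset - gap
    lo = 0 if prev_peak is None else prev_peak
    if hi <= lo:
        hi = window.onset
        lo = max(0, hi - gap)
    seg = values[lo:hi]
    low_level = amp_low + 0.15 * (amp_high - amp_low)
    low = seg[seg < low_level]
    if low.size == 0:
        low = seg
    tail = max(3, int(np.ceil(0.3 * low.size)))
    return float(np.median(low[-tail:]))


def normalize(
    trace: Trace,
    beat_windows: list[BeatWindow],
    flatness_factor: float = 5.0,
) -> NormalizedTrace:
    """Per-beat normalization to dF_n: baseline -> 0, beat peak -> 1.

    ``beat_windows`` come from :func:`cardiomap.features.detect_beats` on
    the same (polarity-corrected, filtered) trace.  Within each window,
    dF_n = (F - baseline) / (peak - baseline), with the baseline taken
    from the pre-upstroke rest segment and the peak the beat maximum.

    Raises :class:`FlatSignalError` when peak - baseline is below
    ``flatness_factor`` times the trace noise estimate (e.g. an ROI on
    background).
    """
    if not beat_windows:
        raise FlatSignalError("no beats to normalize")
    x = np.asarray(trace.values, dtype=float)
    out = x.copy()
    amp_low, amp_high = np.percentile(x, [5, 95])
    floor = flatness_factor * max(noise_estimate(x), 1e-12 * max(abs(amp_high), 1.0))
    refs: list[tuple[float, float]] = []
    prev_peak: int | None = None
    for i, w in enumerate(beat_windows):
        baseline = beat_baseline(x, trace.sample_rate, w, prev_peak, amp_low, amp_high)
        peak = float(x[w.onset : w.end].max())
        if peak - baseline < floor:
            raise FlatSignalError(
                f"beat {i}: peak - baseline = {peak - baseline:.3g} below "
                f"flatness threshold {floor:.3g}"
            )
        lo = w.onset if i > 0 else 0
        hi = w.end if i < len(beat_windows) - 1 else x.size
        out[lo:hi] = (x[lo:hi] - baseline) / (peak - baseline)
        refs.append((baseline, peak))
        prev_peak = w.peak
    return NormalizedTrace(
        values=out,
        sample_rate=trace.sample_rate,
        chamber=trace.chamber,
        modality=trace.modality,
        polarity="positive",
        beat_refs=refs,
    )


__all__ = [
    "temporal_lowpass",
    "spatial_boxfilter",
    "extract_roi_trace",
    "apply_polarity",
    "normalize",
    "noise_estimate",
]
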