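"""Beat segmentation and per-beat electrophysiological features.

Features follow the optical-mapping definitions: heart rate from
peak-to-peak times, activation at the point of maximal normalized
upstroke slope (dF_n/dt_max), and duration at 80 % recovery (APD80 for
voltage, CaTD80 for calcium) from the activation point to the first
post-peak crossing of dF_n = 0.2.

Two summarization protocols are supported: beat-to-beat measurement with
averaging over ten consecutive beats (the in vivo larval protocol) and
signal averaging of ten beats aligned at their activation points before
measuring (the ex vivo adult protocol).
"""

from __future__ import annotations

import numpy as np

from .containers import (
    Activation,
    AveragedWaveform,
    BeatFeatures,
    BeatWindow,
    Chamber,
    Modality,
    Trace,
)
from .errors import (
    AlignmentError,
    DegenerateBeatError,
    InsufficientBeatsError,
    NoRhythmError,
    OrderingError,
    UnterminatedBeatError,
)

#: relative tolerance within which derivative samples count as tied at the
#: maximum (a constant-slope ramp ties across its whole mid-section; the
#: activation point is then the midpoint of the earliest tied run)
_SLOPE_TIE_RTOL = 1e-9


def detect_beats(
    trace: Trace,
    threshold_fraction: float = 0.5,
    refractory_fraction: float = 0.4,
    onset_fraction: float = 0.1,
) -> list[BeatWindow]:
    """Segment a filtered, polarity-corrected trace into beat windows.

    Peaks are found from upward crossings of ``threshold_fraction`` of the
    robust amplitude (5th-95th percentile range) with a refractory period
    of ``refractory_fraction`` of the median cycle length; windows run
    from each beat's upstroke onset to the next beat's onset, and partial
    boundary beats are discarded.
    """
    x = np.asarray(trace.values, dtype=float)
    p5, p95 = np.percentile(x, [5, 95])
    amp = p95 - p5
    thr = p5 + threshold_fraction * amp
    above = x >= thr
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if crossings.size < 2:
        raise NoRhythmError(f"only {crossings.size} threshold crossing(s) found")

    # refractory pass against the median inter-crossing interval
    median_cycle = float(np.median(np.diff(crossings)))
    refractory = refractory_fraction * median_cycle
    accepted = [int(crossings[0])]
    for c in crossings[1:]:
        if c - accepted[-1] >= refractory:
            accepted.append(int(c))
    if len(accepted) < 2:
        raise NoRhythmError("fewer than 2 beats after refractory filtering")
    median_cycle = float(np.median(np.diff(accepted)))

    n = x.size
    onset_level = p5 + onset_fraction * amp
    onsets, peaks = [], []
    for i, c in enumerate(accepted):
        nxt = accepted[i + 1] if i + 1 < len(accepted) else min(
            n, c + int(round(median_cycle))
        )
        peak = c + int(np.argmax(x[c:nxt]))
        # refine to the midpoint of the contiguous top region: on
        # round-topped beats the raw argmax jitters across the whole top
        # under noise, which biases peak-to-peak heart rates
        top = x[peak] - 0.05 * amp
        lo_i = hi_i = peak
        while lo_i - 1 > c and x[lo_i - 1] >= top:
            lo_i -= 1
        while hi_i + 1 < nxt and x[hi_i + 1] >= top:
            hi_i += 1
        peak = (lo_i + hi_i) // 2
        # walk back from the crossing to the start of the ascent
        j = c
        while j > 0 and x[j - 1] > onset_level:
            j -= 1
        if j == 0 and x[0] > onset_level:
            continue  # partial beat at the left boundary
        onsets.append(j)
        peaks.append(peak)

    # crossings that walk back to the same onset belong to one beat
    # (noise re-crossing the threshold mid-beat): merge, keeping the
    # highest peak
    merged: dict[int, int] = {}
    for o, p in zip(onsets, peaks):
        if o in merged:
            merged[o] = p if x[p] > x[merged[o]] else merged[o]
        else:
            merged[o] = p
    onsets = sorted(merged)
    peaks = [merged[o] for o in onsets]

    windows: list[BeatWindow] = []
    for k in range(len(onsets) - 1):
        windows.append(BeatWindow(onsets[k], peaks[k], onsets[k + 1]))
    # the last beat is complete only if a full cycle fits before the end
    if onsets:
        virtual_end = onsets[-1] + int(round(median_cycle))
        if virtual_end <= n:
            windows.append(BeatWindow(onsets[-1], peaks[-1], virtual_end))
    if len(windows) < 2:
        raise NoRhythmError("fewer than 2 complete beats")
    return windows


def heart_rate(peak_times_ms: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Per-interval heart rate (bpm) from peak-to-peak times, with the
    mean and SEM over the intervals.

    Returns ``(per_interval_hr, mean_hr, sem_hr)``.
    """
    t = np.asarray(peak_times_ms, dtype=float)
    if t.size < 2:
        raise NoRhythmError("need at least 2 peaks for a heart rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise OrderingError("peak times must be strictly increasing")
    hr = 60000.0 / dt
    sem = float(hr.std(ddof=1) / np.sqrt(hr.size)) if hr.size > 1 else 0.0
    return hr, float(hr.mean()), sem


def _tied_run_midpoint(d: np.ndarray) -> tuple[float, float]:
    """Index (possibly fractional) and value of the derivative maximum,
    taking the midpoint of the earliest run of tied maxima."""
    dmax = float(d.max())
    tol = abs(dmax) * _SLOPE_TIE_RTOL
    tied = d >= dmax - tol
    first = int(np.argmax(tied))
    last = first
    while last + 1 < d.size and tied[last + 1]:
        last += 1
    return (first + last) / 2.0, dmax


def activation(trace: Trace, beat: BeatWindow) -> Activation:
    """Activation point of one (normalized) beat: time and magnitude of
    the maximal upstroke slope, by central differences."""
    x = np.asarray(trace.values, dtype=float)
    dt_ms = trace.dt_ms
    # gradient strictly inside the beat window: per-beat normalization can
    # leave small scale steps at window boundaries that a cross-boundary
    # central difference would turn into spurious slope spikes
    d = np.gradient(x[beat.onset : beat.end], dt_ms / 1000.0)  # 1/s
    search = d[: beat.peak - beat.onset + 1]
    if search.size == 0 or search.max() <= 0:
        raise DegenerateBeatError("no positive upstroke slope in beat")
    idx, slope = _tied_run_midpoint(search)
    time_ms = (beat.onset + idx) * dt_ms
    return Activation(
        time_ms=time_ms,
        slope=slope,
        peak_time_ms=beat.peak * dt_ms,
        peak_value=float(x[beat.peak]),
    )


def duration80(
    trace: Trace, act: Activation, beat: BeatWindow, level: float = 0.2
) -> float:
    """Duration (ms) from the activation point to the first post-peak
    crossing of ``level`` (0.2 = 80 % recovery from peak toward rest), with
    linear interpolation between samples."""
    x = np.asarray(trace.values, dtype=float)
    seg = x[beat.peak : beat.end]
    below = np.flatnonzero(seg < level)
    below = below[below > 0]
    if below.size == 0:
        raise UnterminatedBeatError(
            "beat does not recover to the 80% level inside its window"
        )
    i = int(below[0])
    x0, x1 = seg[i - 1], seg[i]
    frac = (x0 - level) / (x0 - x1) if x1 != x0 else 0.0
    t80_ms = (beat.peak + i - 1 + frac) * trace.dt_ms
    return float(t80_ms - act.time_ms)


def summarize_beats(
    hr_bpm: np.ndarray,
    upstroke_speed: np.ndarray,
    duration80_ms: np.ndarray,
    *,
    modality: Modality,
    chamber: Chamber,
    n_beats: int = 10,
) -> BeatFeatures:
    """Select the first ``n_beats`` values of each per-beat feature and
    summarize as mean +/- SEM (sd / sqrt(n))."""
    out = {}
    arrays = {}
    for name, arr in (
        ("hr_bpm", hr_bpm),
        ("upstroke_speed", upstroke_speed),
        ("duration80_ms", duration80_ms),
    ):
        a = np.asarray(arr, dtype=float)
        if a.size < n_beats:
            raise InsufficientBeatsError(
                f"{name}: {a.size} beats available, {n_beats} required"
            )
        a = a[:n_beats]
        arrays[name] = a
        out[name] = (float(a.mean()), float(a.std(ddof=1) / np.sqrt(a.size)))
    return BeatFeatures(
        modality=modality,
        chamber=chamber,
        hr_bpm=arrays["hr_bpm"],
        upstroke_speed=arrays["upstroke_speed"],
        duration80_ms=arrays["duration80_ms"],
        summary=out,
    )


def signal_average(
    trace: Trace,
    beats: list[BeatWindow],
    activations: list[Activation],
    min_fraction: float = 0.5,
) -> AveragedWaveform:
    """Average beats aligned at their activation points (t = 0).

    Each beat is resampled by linear interpolation onto the native sample
    grid shifted so its activation time sits at zero; the pointwise mean
    is taken where at least ``min_fraction`` of the beats contribute.
    """
    if len(beats) < 2 or len(beats) != len(activations):
        raise AlignmentError("need >= 2 beats with activations to average")
    dt = trace.dt_ms
    x = np.asarray(trace.values, dtype=float)
    lo = min(b.onset * dt - a.time_ms for b, a in zip(beats, activations))
    hi = max((b.end - 1) * dt - a.time_ms for b, a in zip(beats, activations))
    axis = np.arange(np.ceil(lo / dt), np.floor(hi / dt) + 1) * dt
    if axis.size == 0:
        raise AlignmentError("empty alignment axis")

    acc = np.zeros(axis.size)
    cnt = np.zeros(axis.size, dtype=int)
    for b, a in zip(beats, activations):
        t_beat = np.arange(b.onset, b.end) * dt - a.time_ms
        m = (axis >= t_beat[0]) & (axis <= t_beat[-1])
        acc[m] += np.interp(axis[m], t_beat, x[b.onset : b.end])
        cnt[m] += 1
    need = max(2, int(np.ceil(min_fraction * len(beats))))
    valid = cnt >= need
    if not valid.any():
        raise AlignmentError("no axis points with enough contributing beats")
    i0, i1 = np.flatnonzero(valid)[[0, -1]]
    return AveragedWaveform(
        times_ms=axis[i0 : i1 + 1],
        values=acc[i0 : i1 + 1] / cnt[i0 : i1 + 1],
        sample_rate=trace.sample_rate,
        n_beats=len(beats),
        chamber=trace.chamber,
        modality=trace.modality,
    )


def features_from_average(avg: AveragedWaveform) -> tuple[Activation, float]:
    """Measure activation and duration80 on an averaged waveform.

    The average of normalized beats is renormalized first: its baseline is
    0 by construction (each beat was normalized to baseline 0), but noise
    and beat-to-beat alignment jitter smear the averaged peak slightly
    below 1, so only the peak is rescaled before measuring with the same
    estimators as single beats.
    """
    y = avg.values.copy()
    peak_idx = int(np.argmax(y))
    peak = float(y[peak_idx])
    y = y / peak
    tr = Trace(y, avg.sample_rate, avg.chamber, avg.modality)
    window = BeatWindow(0, peak_idx, y.size)
    act = activation(tr, window)
    d80 = duration80(tr, act, window)
    return act, d80


__all__ = [
    "detect_beats",
    "heart_rate",
    "activation",
    "duration80",
    "summarize_beats",
    "signal_average",
    "features_from_average",
]
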