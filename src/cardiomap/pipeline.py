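"""End-to-end analysis of one two-chamber recording.

Runs the preprocessing chain, beat segmentation, per-beat feature
extraction, and AV-conduction analysis, applying the stage-appropriate
summarization protocol: beat-to-beat averaging over ten consecutive beats
for larval recordings, or signal averaging of ten beats aligned at their
activation points for adult recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import features as ft
from . import preprocess as pp
from . import rhythm as rh
from .containers import (
    BeatWindow,
    Chamber,
    FrameStack,
    Modality,
    ROISpec,
    Trace,
)
from .errors import CardiomapError, ConfigError, InsufficientBeatsError
from .synth import ChamberGeometry


@dataclass
class AnalysisSettings:
    """Tunable parameters of the analysis chain (defaults follow the
    published protocol: 50 Hz low-pass, 5x5 spatial box, ten beats)."""

    stage: str = "larva"
    cutoff_hz: float = 50.0
    filter_order: int = 4
    spatial_size: int = 5
    spatial_first: bool = True
    n_beats: int = 10
    threshold_fraction: float = 0.5
    refractory_fraction: float = 0.4
    max_lag_ms: float | None = None
    alternation_threshold: float = 0.8
    hr_chamber: Chamber = "atrium"


@dataclass
class ChamberResult:
    """Summary features for one chamber of one recording."""

    chamber: Chamber
    modality: Modality
    protocol: str  # "beat-averaged" or "signal-averaged"
    n_beats: int
    hr_mean_bpm: float
    hr_sem_bpm: float
    upstroke_mean: float
    upstroke_sem: float
    duration80_mean_ms: float
    duration80_sem_ms: float
    per_beat_upstroke: np.ndarray | None = None
    per_beat_duration80: np.ndarray | None = None
    excluded_beats: list[str] = field(default_factory=list)


@dataclass
class RecordingResult:
    """Full result for one recording: both chambers plus rhythm."""

    stage: str
    modality: Modality
    atrium: ChamberResult
    ventricle: ChamberResult
    rhythm: rh.RhythmReport
    hr_mean_bpm: float  # from the configured HR chamber (atrial by default)
    hr_sem_bpm: float

    def to_dict(self) -> dict:
        def cham(c: ChamberResult) -> dict:
            return {
                "chamber": c.chamber,
                "protocol": c.protocol,
                "n_beats": c.n_beats,
                "hr_mean_bpm": c.hr_mean_bpm,
                "hr_sem_bpm": c.hr_sem_bpm,
                "upstroke_mean": c.upstroke_mean,
                "upstroke_sem": c.upstroke_sem,
                "duration80_mean_ms": c.duration80_mean_ms,
                "duration80_sem_ms": c.duration80_sem_ms,
                "excluded_beats": c.excluded_beats,
            }

        return {
            "stage": self.stage,
            "modality": self.modality,
            "hr_mean_bpm": self.hr_mean_bpm,
            "hr_sem_bpm": self.hr_sem_bpm,
            "atrium": cham(self.atrium),
            "ventricle": cham(self.ventricle),
            "rhythm": {
                "conduction_ratio": list(self.rhythm.conduction_ratio),
                "block_flag": self.rhythm.block_flag,
                "pattern": self.rhythm.pattern,
                "av_delay_mean_ms": self.rhythm.av_delay_mean_ms,
                "av_delay_sem_ms": self.rhythm.av_delay_sem_ms,
                "n_pairs": self.rhythm.n_pairs,
            },
        }


def _measure_beats(
    norm: Trace, windows: list[BeatWindow]
) -> tuple[list[ft.Activation], np.ndarray, list[str]]:
    """Per-beat activation and duration80, excluding (and logging)
    unterminated beats."""
    acts: list[ft.Activation] = []
    d80s: list[float] = []
    excluded: list[str] = []
    for i, w in enumerate(windows):
        try:
            act = ft.activation(norm, w)
            d80 = ft.duration80(norm, act, w)
        except CardiomapError as e:
            excluded.append(f"beat {i}: {e}")
            acts.append(None)  # type: ignore[arg-type]
            d80s.append(math.nan)
            continue
        acts.append(act)
        d80s.append(d80)
    return acts, np.asarray(d80s), excluded


def analyze_chamber(
    trace: Trace, settings: AnalysisSettings
) -> tuple[ChamberResult, list[BeatWindow], list[ft.Activation]]:
    """Preprocess and measure one chamber trace.

    Returns the chamber summary plus the beat windows and per-beat
    activations (with absolute times) for downstream AV pairing.
    """
    tr = pp.apply_polarity(trace)
    tr = pp.temporal_lowpass(tr, settings.cutoff_hz, settings.filter_order)
    windows = ft.detect_beats(
        tr,
        threshold_fraction=settings.threshold_fraction,
        refractory_fraction=settings.refractory_fraction,
    )
    norm = pp.normalize(tr, windows)
    acts, d80s, excluded = _measure_beats(norm, windows)

    valid = [i for i, a in enumerate(acts) if a is not None and not math.isnan(d80s[i])]
    n = settings.n_beats
    if len(valid) < n:
        raise InsufficientBeatsError(
            f"{trace.chamber}: {len(valid)} usable beats, {n} required"
        )
    sel = valid[:n]
    # HR needs n intervals = n+1 peaks when available, else n peaks
    peak_candidates = valid[: n + 1] if len(valid) > n else valid
    peak_times = np.array([windows[i].peak for i in peak_candidates]) * norm.dt_ms
    hr_per, hr_mean, hr_sem = ft.heart_rate(peak_times)

    up = np.array([acts[i].slope for i in sel])
    dd = np.array([d80s[i] for i in sel])

    if settings.stage == "adult":
        avg = ft.signal_average(norm, [windows[i] for i in sel], [acts[i] for i in sel])
        act_avg, d80_avg = ft.features_from_average(avg)
        res = ChamberResult(
            chamber=trace.chamber,
            modality=trace.modality,
            protocol="signal-averaged",
            n_beats=len(sel),
            hr_mean_bpm=hr_mean,
            hr_sem_bpm=hr_sem,
            upstroke_mean=act_avg.slope,
            upstroke_sem=math.nan,
            duration80_mean_ms=d80_avg,
            duration80_sem_ms=math.nan,
            per_beat_upstroke=up,
            per_beat_duration80=dd,
            excluded_beats=excluded,
        )
    else:
        hr_in = hr_per if hr_per.size >= n else np.full(n, hr_mean)
        summary = ft.summarize_beats(
            hr_in,
            up,
            dd,
            modality=trace.modality,
            chamber=trace.chamber,
            n_beats=n,
        )
        res = ChamberResult(
            chamber=trace.chamber,
            modality=trace.modality,
            protocol="beat-averaged",
            n_beats=n,
            hr_mean_bpm=hr_mean,
            hr_sem_bpm=hr_sem,
            upstroke_mean=summary.summary["upstroke_speed"][0],
            upstroke_sem=summary.summary["upstroke_speed"][1],
            duration80_mean_ms=summary.summary["duration80_ms"][0],
            duration80_sem_ms=summary.summary["duration80_ms"][1],
            per_beat_upstroke=up,
            per_beat_duration80=dd,
            excluded_beats=excluded,
        )
    return res, windows, acts


def analyze_pair(
    atrial: Trace, ventricular: Trace, settings: AnalysisSettings | None = None
) -> RecordingResult:
    """Analyze a paired atrial + ventricular recording end to end."""
    settings = settings or AnalysisSettings()
    res_a, win_a, acts_a = analyze_chamber(atrial, settings)
    res_v, win_v, acts_v = analyze_chamber(ventricular, settings)

    times_a = [a.time_ms for a in acts_a if a is not None]
    times_v = [a.time_ms for a in acts_v if a is not None]
    pairing = rh.pair_activations(times_a, times_v, settings.max_lag_ms)
    report = rh.conduction_ratio(pairing, settings.alternation_threshold)

    hr_src = res_a if settings.hr_chamber == "atrium" else res_v
    return RecordingResult(
        stage=settings.stage,
        modality=atrial.modality,
        atrium=res_a,
        ventricle=res_v,
        rhythm=report,
        hr_mean_bpm=hr_src.hr_mean_bpm,
        hr_sem_bpm=hr_src.hr_sem_bpm,
    )


def analyze_framestack(
    stack: FrameStack,
    rois: list[ROISpec],
    settings: AnalysisSettings | None = None,
    geometry: ChamberGeometry | None = None,
) -> RecordingResult:
    """Analyze a frame stack: spatial box filter, ROI traces, then the
    trace pipeline.  ``rois`` must contain one atrium and one ventricle
    ROI (``geometry`` can supply default ROI centers for simulated data)."""
    settings = settings or AnalysisSettings()
    if settings.spatial_first:
        stack = pp.spatial_boxfilter(stack, settings.spatial_size)
    by_chamber = {}
    for roi in rois:
        by_chamber[roi.chamber] = pp.extract_roi_trace(stack, roi)
    if set(by_chamber) != {"atrium", "ventricle"}:
        raise ConfigError("need exactly one atrium and one ventricle ROI")
    return analyze_pair(by_chamber["atrium"], by_chamber["ventricle"], settings)


__all__ = [
    "AnalysisSettings",
    "ChamberResult",
    "RecordingResult",
    "analyze_chamber",
    "analyze_pair",
    "analyze_framestack",
]
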