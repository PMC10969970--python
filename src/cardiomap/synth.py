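"""Synthetic two-chamber fluorescence recordings with known ground truth.

The generator emulates dual-chamber cardiac optical mapping of zebrafish
hearts: periodic atrial action potentials / calcium transients, ventricular
beats that follow the atrium after an atrioventricular (AV) conduction
delay (possibly with k:1 block or random conduction failure), additive
Gaussian noise, slow baseline drift, and an optional camera model
(frame stacks with chamber masks and per-pixel noise).

Waveform model
--------------
A single beat is described by :class:`WaveformShape`: a monotonic rise of
total duration ``upstroke_ms``, an optional plateau at the peak, and a
decay that is linear, exponential, or plateau-then-linear.  The rise and
the linear decay are piecewise-linear in their mid sections with
cosine-smoothed derivative edges (``rise_edge_ms``/``decay_edge_ms``):
sharp corners would make the zero-phase Butterworth filter in the analysis
chain ring, which biases the maximal-slope estimate and displaces the
activation point.  All contractual feature values have closed forms that
reduce to the familiar expressions as the edge widths go to zero:

* maximal slope of a rise over ``dt`` ms  ->  ``1000 / dt``  (1/s),
* time of maximal slope  ->  the rise midpoint,
* duration to 80 % recovery for a linear decay over ``D`` ms measured from
  the maximal-slope point  ->  ``(rise)/2 + plateau + 0.8 D``,
* for an exponential decay with time constant ``tau``  ->  ``tau * ln 5``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal

import numpy as np

from .containers import Chamber, FrameStack, Modality, Polarity, Trace
from .errors import (
    GeometryError,
    InsufficientDurationError,
    InvalidShapeError,
    ParameterError,
)

#: fraction of the peak at which an exponential decay is truncated to zero
_EXP_FLOOR = 1e-4

DecayModel = Literal["linear", "exponential", "plateau_then_linear"]


# ---------------------------------------------------------------------------
# waveform shape and closed forms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaveformShape:
    """Generative description of one normalized beat (peak = 1).

    Parameters
    ----------
    upstroke_ms : float
        Total duration of the monotonic rise from baseline to peak, in ms.
        ``0`` means a one-sample (instantaneous) rise.
    decay_model : {"linear", "exponential", "plateau_then_linear"}
        Decay law after the peak/plateau.
    decay_ms : float
        Total decay time for a linear decay (time from peak to baseline at
        the mid-decay slope), or the time constant tau for an exponential.
    plateau_ms : float
        Duration the waveform holds at the peak before decaying.
    amplitude : float
        Peak height in normalized units (the analysis chain renormalizes,
        so this is a pure scale factor).
    rise_edge_ms, decay_edge_ms : float
        Widths of the cosine-smoothed derivative edges of the rise and the
        linear decay.  0 gives exact piecewise-linear segments.
    rise_bump, rise_bump_width_ms : float
        Optional cosine-shaped excess slope at the rise midpoint:
        ``rise_bump`` is the relative extra slope (e.g. 0.15 for +15 %)
        over a window of ``rise_bump_width_ms`` centered on the midpoint.
        This makes the maximal-slope point unique and centered even after
        low-pass filtering (a flat mid-section slope can be locally
        exceeded by filter ringing at the edge transitions).
    """

    upstroke_ms: float
    decay_model: DecayModel = "linear"
    decay_ms: float = 100.0
    plateau_ms: float = 0.0
    amplitude: float = 1.0
    rise_edge_ms: float = 0.0
    decay_edge_ms: float = 0.0
    rise_bump: float = 0.0
    rise_bump_width_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.upstroke_ms < 0:
            raise InvalidShapeError("upstroke_ms must be >= 0")
        if not self.decay_ms > 0:
            raise InvalidShapeError("decay_ms must be positive")
        if self.plateau_ms < 0:
            raise InvalidShapeError("plateau_ms must be >= 0")
        if not self.amplitude > 0:
            raise InvalidShapeError("amplitude must be positive")
        if self.decay_model not in ("linear", "exponential", "plateau_then_linear"):
            raise InvalidShapeError(f"unknown decay model {self.decay_model!r}")
        if self.rise_edge_ms < 0 or self.decay_edge_ms < 0:
            raise InvalidShapeError("edge widths must be >= 0")
        if self.upstroke_ms > 0 and 2 * self.rise_edge_ms > self.upstroke_ms:
            raise InvalidShapeError("rise_edge_ms may not exceed half the rise")
        if self.decay_model != "exponential" and self.decay_edge_ms > 0.4 * self.decay_ms:
            raise InvalidShapeError("decay_edge_ms may not exceed 0.4 * decay_ms")
        if self.rise_bump < 0 or self.rise_bump_width_ms < 0:
            raise InvalidShapeError("rise bump parameters must be >= 0")
        if self.rise_bump > 0 and (
            self.rise_bump_width_ms == 0
            or self.rise_bump_width_ms > self.upstroke_ms - 2 * self.rise_edge_ms
        ):
            raise InvalidShapeError(
                "rise_bump_width_ms must fit inside the flat mid-section"
            )

    # -- closed forms ------------------------------------------------------

    @property
    def _base_slope_per_ms(self) -> float:
        """Mid-section slope s0 of the rise (before the center bump)."""
        if self.upstroke_ms == 0:
            return math.inf
        area_extra = 0.5 * self.rise_bump * self.rise_bump_width_ms
        return 1.0 / (self.upstroke_ms - self.rise_edge_ms + area_extra)

    @property
    def max_slope_per_ms(self) -> float:
        """Maximal rise slope in normalized units per ms (for amplitude 1).

        For an instantaneous rise this is undefined in continuous time and
        reported by :func:`make_waveform` as the sample rate instead.
        """
        if self.upstroke_ms == 0:
            return math.inf
        return self._base_slope_per_ms * (1.0 + self.rise_bump)

    def closed_form_max_slope(self, sample_rate: float) -> float:
        """Maximal slope of the normalized rise, in 1/s."""
        if self.upstroke_ms == 0:
            return float(sample_rate)
        return 1000.0 * self.max_slope_per_ms

    @property
    def activation_time_ms(self) -> float:
        """Time of the maximal-slope point, from the start of the rise.

        A constant-derivative ramp attains its maximum over the whole mid
        section; the convention here is the midpoint of that run, which by
        symmetry is also where the smoothed shapes peak after filtering.
        """
        return self.upstroke_ms / 2.0

    @property
    def peak_time_ms(self) -> float:
        return self.upstroke_ms

    @property
    def decay80_ms(self) -> float:
        """Time from decay onset to the 80 % recovery crossing (level 0.2)."""
        if self.decay_model == "exponential":
            return self.decay_ms * math.log(5.0)
        return 0.8 * self.decay_ms + 0.5 * self.decay_edge_ms

    @property
    def duration80_ms(self) -> float:
        """Closed-form duration from the maximal-slope point to 80 % recovery."""
        return (
            self.upstroke_ms
            - self.activation_time_ms
            + self.plateau_ms
            + self.decay80_ms
        )

    @property
    def support_ms(self) -> float:
        """Total time the waveform is (numerically) nonzero."""
        if self.decay_model == "exponential":
            tail = self.decay_ms * math.log(1.0 / _EXP_FLOOR)
        else:
            tail = self.decay_ms + self.decay_edge_ms
        return self.upstroke_ms + self.plateau_ms + tail

    # -- evaluation --------------------------------------------------------

    def __call__(self, t_ms: np.ndarray) -> np.ndarray:
        """Evaluate the normalized waveform at times ``t_ms`` (ms) measured
        from the start of the rise."""
        t = np.asarray(t_ms, dtype=float)
        y = np.zeros_like(t)
        R, c = self.upstroke_ms, self.rise_edge_ms
        P = self.plateau_ms

        if R > 0:
            s = self._base_slope_per_ms
            if c > 0 or self.rise_bump > 0:
                u = t
                m = (u >= 0) & (u < c)
                y[m] = 0.5 * s * (u[m] - (c / math.pi) * np.sin(math.pi * u[m] / c))
                m = (u >= c) & (u < R - c)
                y[m] = s * (u[m] - c / 2.0)
                m = (u >= R - c) & (u < R)
                w = R - u[m]
                y[m] = 1.0 - 0.5 * s * (w - (c / math.pi) * np.sin(math.pi * w / c))
                if self.rise_bump > 0:
                    # cosine-shaped excess slope centered on the midpoint
                    gb, wb = self.rise_bump, self.rise_bump_width_ms
                    u0 = R / 2.0 - wb / 2.0
                    x = np.clip(u - u0, 0.0, wb)
                    # only below the rise-out edge: the mirror formula there
                    # already accounts for the completed bump area
                    y += np.where(
                        (u >= 0) & (u < R - c),
                        gb * s * 0.5 * (x - (wb / (2 * math.pi)) * np.sin(2 * math.pi * x / wb)),
                        0.0,
                    )
            else:
                m = (t >= 0) & (t < R)
                y[m] = t[m] / R
        else:
            # one-sample rise: a step at t = 0
            y[t >= 0] = 1.0

        y[(t >= R) & (t < R + P)] = 1.0

        v = t - (R + P)
        if self.decay_model == "exponential":
            m = v >= 0
            yy = np.exp(-v[m] / self.decay_ms)
            yy[yy < _EXP_FLOOR] = 0.0
            y[m] = yy
        else:
            D, cd = self.decay_ms, self.decay_edge_ms
            sd = 1.0 / (D - cd) if cd > 0 else 1.0 / D
            if cd > 0:
                m = (v >= 0) & (v < cd)
                y[m] = 1.0 - 0.5 * sd * (
                    v[m] - (cd / math.pi) * np.sin(math.pi * v[m] / cd)
                )
                m = (v >= cd) & (v < D)
                y[m] = 1.0 - sd * (v[m] - cd / 2.0)
                m = (v >= D) & (v < D + cd)
                w = D + cd - v[m]
                y[m] = 0.5 * sd * (w - (cd / math.pi) * np.sin(math.pi * w / cd))
                y[v >= D + cd] = 0.0
            else:
                m = (v >= 0) & (v < D)
                y[m] = 1.0 - v[m] / D
                y[v >= D] = 0.0
        return self.amplitude * np.clip(y, 0.0, None)


@dataclass(frozen=True)
class WaveformTemplate:
    """A sampled single-beat template with its closed-form features."""

    samples: np.ndarray
    sample_rate: float
    max_slope: float  # 1/s
    duration80_ms: float
    activation_time_ms: float
    peak_time_ms: float


def make_waveform(shape: WaveformShape, sample_rate: float) -> WaveformTemplate:
    """Sample a single-beat template and report its closed-form features.

    The template starts and ends at zero and peaks at ``shape.amplitude``.
    The reported ``max_slope`` and ``duration80_ms`` are the continuous-time
    closed forms of the shape (for a one-sample rise, ``max_slope`` is the
    sample rate and the activation point is the rise itself).
    """
    if not sample_rate > 0:
        raise ParameterError("sample_rate must be positive")
    dt = 1000.0 / sample_rate
    if shape.upstroke_ms == 0:
        # sample so the step lands between the first two samples
        n = int(math.ceil(shape.support_ms / dt)) + 3
        t = np.arange(n) * dt - dt
        samples = shape(t)
        act = 0.0
        d80 = shape.plateau_ms + shape.decay80_ms
        peak = 0.0
    else:
        n = int(math.ceil(shape.support_ms / dt)) + 2
        t = np.arange(n) * dt
        samples = shape(t)
        act = shape.activation_time_ms
        d80 = shape.duration80_ms
        peak = shape.peak_time_ms
    samples[-1] = 0.0
    return WaveformTemplate(
        samples=samples,
        sample_rate=sample_rate,
        max_slope=shape.closed_form_max_slope(sample_rate),
        duration80_ms=d80,
        activation_time_ms=act,
        peak_time_ms=peak,
    )


# ---------------------------------------------------------------------------
# conduction and simulation parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConductionPattern:
    """AV conduction: ``ratio_numerator`` atrial beats per
    ``ratio_denominator`` conducted ventricular beats (1:1, 2:1, ...),
    optional random conduction failure, and the AV delay statistics."""

    ratio_numerator: int = 1
    ratio_denominator: int = 1
    dropout_probability: float = 0.0
    av_delay_ms: float = 70.0
    av_delay_jitter_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.ratio_numerator < 1 or self.ratio_denominator < 1:
            raise ParameterError("conduction ratio components must be >= 1")
        if not 0.0 <= self.dropout_probability <= 1.0:
            raise ParameterError("dropout_probability must be in [0, 1]")
        if self.av_delay_ms < 0:
            raise ParameterError("av_delay_ms must be >= 0")
        if self.av_delay_jitter_ms < 0:
            raise ParameterError("av_delay_jitter_ms must be >= 0")

    def conducted(self, n_atrial: int) -> np.ndarray:
        """Boolean mask over atrial beats: which are conducted under the
        integer ratio (before random dropout)."""
        k = np.arange(n_atrial)
        num, den = self.ratio_numerator, self.ratio_denominator
        # first atrial beat conducts; then den out of every num
        return (k * den) % num < den


#: temporal low-pass cutoff assumed by the analysis chain (Hz); the sampling
#: rate must stay above twice this value.
ANALYSIS_CUTOFF_HZ = 50.0


@dataclass(frozen=True)
class SimParams:
    """Full generative description of a two-chamber recording.

    One recording carries a single modality (``Vm`` or ``Ca``); the four
    waveform shapes (chamber x modality) are all stored so a preset can
    describe both recording types of a study group.
    """

    atrial_rate_bpm: float
    atrium_vm: WaveformShape
    ventricle_vm: WaveformShape
    atrium_ca: WaveformShape
    ventricle_ca: WaveformShape
    conduction: ConductionPattern = field(default_factory=ConductionPattern)
    modality: Modality = "Vm"
    sample_rate_hz: float = 500.0
    duration_s: float = 10.0
    noise_sd: float = 0.0
    drift_amplitude: float = 0.0
    drift_period_s: float = 5.0
    polarity: Polarity = "positive"
    lead_in_ms: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.atrial_rate_bpm > 0:
            raise ParameterError("atrial_rate_bpm must be positive")
        if self.sample_rate_hz <= 2 * ANALYSIS_CUTOFF_HZ:
            raise ParameterError(
                f"sample_rate_hz must exceed twice the {ANALYSIS_CUTOFF_HZ} Hz "
                "analysis cutoff"
            )
        if self.duration_s * self.atrial_rate_bpm / 60.0 < 11:
            raise InsufficientDurationError(
                "recording too short: fewer than 11 atrial beats "
                f"({self.duration_s} s at {self.atrial_rate_bpm} bpm)"
            )
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ParameterError("noise_sd and drift_amplitude must be >= 0")
        if not self.drift_period_s > 0:
            raise ParameterError("drift_period_s must be positive")
        if self.seed is None:
            raise ParameterError("a seed is mandatory")

    @property
    def cycle_ms(self) -> float:
        return 60000.0 / self.atrial_rate_bpm

    def waveform(self, chamber: Chamber, modality: Modality | None = None) -> WaveformShape:
        modality = modality or self.modality
        key = f"{'atrium' if chamber == 'atrium' else 'ventricle'}_{modality.lower()}"
        return getattr(self, key)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@lru_cache(maxsize=512)
def chain_references(
    shape: WaveformShape, sample_rate: float, cutoff_hz: float = ANALYSIS_CUTOFF_HZ
) -> tuple[float, float, float]:
    """Deterministic noiseless references for the measured beat features.

    Pushes the noiseless single-beat template through the analysis chain's
    zero-phase low-pass filter and feature estimators and returns
    ``(upstroke_speed, activation_offset_ms, duration80_ms)``, where the
    activation offset is measured from the start of the rise.

    These are the values the chain reports in the absence of noise: the
    filter attenuates rises faster than its own step response can follow,
    so for fast upstrokes the measured slope falls below the template's
    closed form (ceiling ~2*fc*int dx/(1+x^8) ~ 103 1/s at 50 Hz for unit
    amplitude).
    """
    from scipy.signal import butter, filtfilt

    from .containers import BeatWindow, Trace
    from .features import activation as _activation
    from .features import duration80 as _duration80

    dt = 1000.0 / sample_rate
    pad = int(round(150.0 / dt))
    tmpl = make_waveform(shape, sample_rate).samples / shape.amplitude
    x = np.concatenate([np.zeros(pad), tmpl, np.zeros(pad)])
    b, a = butter(4, cutoff_hz / (sample_rate / 2.0))
    f = filtfilt(b, a, x)
    f = f / f.max()
    peak = int(np.argmax(f))
    onset = peak
    while onset > 0 and f[onset - 1] > 0.02:
        onset -= 1
    tr = Trace(f, sample_rate)
    window = BeatWindow(onset, peak, f.size)
    act = _activation(tr, window)
    d80 = _duration80(tr, act, window)
    rise_start = (pad + 1) * dt if shape.upstroke_ms == 0 else pad * dt
    return float(act.slope), float(act.time_ms - rise_start), float(d80)


def chain_reference_upstroke(
    shape: WaveformShape, sample_rate: float, cutoff_hz: float = ANALYSIS_CUTOFF_HZ
) -> float:
    """Noiseless-chain upstroke speed (see :func:`chain_references`)."""
    return chain_references(shape, sample_rate, cutoff_hz)[0]


@dataclass
class GroundTruth:
    """True generative values for one simulated recording.

    ``upstroke_speed`` and ``duration80_ms`` hold, per chamber, the values
    the analysis chain measures on the noiseless waveform (the
    identifiable references), while ``template_max_slope`` and
    ``template_duration80_ms`` hold the closed forms of the underlying
    template; they agree closely except for rises faster than the 50 Hz
    filter's response ceiling.  Heart rates, the AV delay and the
    activation-time lists equal the closed-form properties of the
    schedule.
    """

    modality: Modality
    hr_bpm: dict[Chamber, float]
    av_delay_ms: float
    upstroke_speed: dict[Chamber, float]
    template_max_slope: dict[Chamber, float]
    duration80_ms: dict[Chamber, float]
    template_duration80_ms: dict[Chamber, float]
    atrial_activation_times_ms: np.ndarray
    ventricular_activation_times_ms: np.ndarray

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "hr_bpm": dict(self.hr_bpm),
            "av_delay_ms": self.av_delay_ms,
            "upstroke_speed": dict(self.upstroke_speed),
            "template_max_slope": dict(self.template_max_slope),
            "duration80_ms": dict(self.duration80_ms),
            "template_duration80_ms": dict(self.template_duration80_ms),
            "atrial_activation_times_ms": list(map(float, self.atrial_activation_times_ms)),
            "ventricular_activation_times_ms": list(
                map(float, self.ventricular_activation_times_ms)
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            modality=d["modality"],
            hr_bpm=d["hr_bpm"],
            av_delay_ms=d["av_delay_ms"],
            upstroke_speed=d["upstroke_speed"],
            template_max_slope=d["template_max_slope"],
            duration80_ms=d["duration80_ms"],
            template_duration80_ms=d["template_duration80_ms"],
            atrial_activation_times_ms=np.asarray(d["atrial_activation_times_ms"]),
            ventricular_activation_times_ms=np.asarray(
                d["ventricular_activation_times_ms"]
            ),
        )


# ---------------------------------------------------------------------------
# trace simulation
# ---------------------------------------------------------------------------


def _schedule(params: SimParams, rng: np.random.Generator):
    """Atrial/ventricular activation times and rise starts (ms)."""
    a_shape = params.waveform("atrium")
    v_shape = params.waveform("ventricle")
    duration_ms = params.duration_s * 1000.0
    cycle = params.cycle_ms

    first_rise = params.lead_in_ms
    n_atrial = int(math.floor((duration_ms - first_rise) / cycle)) + 1
    a_rise = first_rise + np.arange(n_atrial) * cycle
    a_act = a_rise + a_shape.activation_time_ms

    cond = params.conduction
    mask = cond.conducted(n_atrial)
    if cond.dropout_probability > 0:
        drop = rng.random(n_atrial) < cond.dropout_probability
        mask = mask & ~drop
    jitter = rng.normal(0.0, cond.av_delay_jitter_ms, n_atrial)
    delays = np.clip(cond.av_delay_ms + jitter, 1.0, None)
    v_act = (a_act + delays)[mask]
    v_rise = v_act - v_shape.activation_time_ms
    keep = v_rise + v_shape.activation_time_ms < duration_ms
    return a_rise, a_act, v_rise[keep], v_act[keep]


def _render(rise_starts: np.ndarray, shape: WaveformShape, n: int, dt: float) -> np.ndarray:
    """Sum of single-beat templates at the given rise starts (sample units)."""
    sig = np.zeros(n)
    support = shape.support_ms
    for t0 in rise_starts:
        i0 = max(0, int(math.floor(t0 / dt)) - 1)
        i1 = min(n, int(math.ceil((t0 + support) / dt)) + 2)
        if i1 <= i0:
            continue
        t = np.arange(i0, i1) * dt - t0
        sig[i0:i1] += shape(t)
    return sig


def _ground_truth(params: SimParams, a_act, v_act) -> GroundTruth:
    a_shape = params.waveform("atrium")
    v_shape = params.waveform("ventricle")
    cond = params.conduction
    v_rate = (
        params.atrial_rate_bpm * cond.ratio_denominator / cond.ratio_numerator
    ) * (1.0 - cond.dropout_probability)
    up_a, _, d80_a = chain_references(a_shape, params.sample_rate_hz)
    up_v, _, d80_v = chain_references(v_shape, params.sample_rate_hz)
    return GroundTruth(
        modality=params.modality,
        hr_bpm={"atrium": params.atrial_rate_bpm, "ventricle": v_rate},
        av_delay_ms=cond.av_delay_ms,
        upstroke_speed={"atrium": up_a, "ventricle": up_v},
        template_max_slope={
            "atrium": a_shape.closed_form_max_slope(params.sample_rate_hz),
            "ventricle": v_shape.closed_form_max_slope(params.sample_rate_hz),
        },
        duration80_ms={"atrium": d80_a, "ventricle": d80_v},
        template_duration80_ms={
            "atrium": a_shape.duration80_ms,
            "ventricle": v_shape.duration80_ms,
        },
        atrial_activation_times_ms=a_act,
        ventricular_activation_times_ms=v_act,
    )


def simulate_recording(params: SimParams) -> tuple[Trace, Trace, GroundTruth]:
    """Simulate a paired atrial + ventricular trace recording (one modality).

    Returns ``(atrial_trace, ventricular_trace, ground_truth)``.  Identical
    parameters (including the seed) give bit-identical outputs.
    """
    rng = np.random.default_rng(params.seed)
    dt = 1000.0 / params.sample_rate_hz
    n = int(round(params.duration_s * 1000.0 / dt))

    a_rise, a_act, v_rise, v_act = _schedule(params, rng)

    a_shape = params.waveform("atrium")
    v_shape = params.waveform("ventricle")
    sig_a = _render(a_rise, a_shape, n, dt)
    sig_v = _render(v_rise, v_shape, n, dt)

    t_s = np.arange(n) * dt / 1000.0
    drift_phase = rng.uniform(0, 2 * math.pi)
    drift = params.drift_amplitude * np.sin(
        2 * math.pi * t_s / params.drift_period_s + drift_phase
    )
    noise_a = rng.normal(0.0, params.noise_sd, n) if params.noise_sd else 0.0
    noise_v = rng.normal(0.0, params.noise_sd, n) if params.noise_sd else 0.0

    sign = -1.0 if params.polarity == "negative" else 1.0
    vals_a = sign * sig_a + drift + noise_a
    vals_v = sign * sig_v + drift + noise_v

    tr_a = Trace(vals_a, params.sample_rate_hz, "atrium", params.modality, params.polarity)
    tr_v = Trace(vals_v, params.sample_rate_hz, "ventricle", params.modality, params.polarity)
    return tr_a, tr_v, _ground_truth(params, a_act, v_act)


# ---------------------------------------------------------------------------
# frame-stack simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChamberGeometry:
    """Two labeled elliptical chamber masks on a pixel grid."""

    grid: tuple[int, int] = (128, 128)
    atrium_center: tuple[float, float] = (64.0, 34.0)
    atrium_axes: tuple[float, float] = (26.0, 22.0)
    ventricle_center: tuple[float, float] = (64.0, 92.0)
    ventricle_axes: tuple[float, float] = (30.0, 26.0)

    def masks(self) -> tuple[np.ndarray, np.ndarray]:
        rr, cc = np.mgrid[0 : self.grid[0], 0 : self.grid[1]]

        def ellipse(center, axes):
            return ((rr - center[0]) / axes[0]) ** 2 + (
                (cc - center[1]) / axes[1]
            ) ** 2 <= 1.0

        ma = ellipse(self.atrium_center, self.atrium_axes)
        mv = ellipse(self.ventricle_center, self.ventricle_axes)
        if (ma & mv).any():
            raise GeometryError("chamber masks overlap")
        return ma, mv

    def roi_center(self, chamber: Chamber) -> tuple[int, int]:
        c = self.atrium_center if chamber == "atrium" else self.ventricle_center
        return (int(round(c[0])), int(round(c[1])))

    @classmethod
    def default_for_grid(cls, grid: tuple[int, int]) -> "ChamberGeometry":
        """Scale the default 128 x 128 layout to another grid size."""
        sr, sc = grid[0] / 128.0, grid[1] / 128.0

        def sc2(p, fr=sr, fc=sc):
            return (p[0] * fr, p[1] * fc)

        d = cls()
        return cls(
            grid=grid,
            atrium_center=sc2(d.atrium_center),
            atrium_axes=sc2(d.atrium_axes),
            ventricle_center=sc2(d.ventricle_center),
            ventricle_axes=sc2(d.ventricle_axes),
        )


#: 16-bit camera model: background offset and signal gain in counts
_CAMERA_OFFSET = 2000.0
_CAMERA_GAIN = 30000.0


def simulate_framestack(
    params: SimParams,
    geometry: ChamberGeometry | None = None,
    min_roi_window: int = 5,
) -> tuple[FrameStack, GroundTruth]:
    """Simulate a 16-bit camera frame stack of a two-chamber recording.

    Every pixel inside a chamber mask carries that chamber's (noiseless)
    trace scaled into the camera's intensity range plus independent
    Gaussian pixel noise of sd ``params.noise_sd`` (in normalized signal
    units, i.e. multiplied by the camera gain); background pixels carry
    the offset plus noise.  ``params.drift_amplitude`` wanders the whole
    field.  Quantization to 16-bit counts is the only nonlinearity.
    """
    geometry = geometry or ChamberGeometry()
    mask_a, mask_v = geometry.masks()
    for name, m in (("atrium", mask_a), ("ventricle", mask_v)):
        # the ROI window must fit inside the mask around its center
        r, c = geometry.roi_center(name)  # type: ignore[arg-type]
        h = min_roi_window // 2
        sub = m[r - h : r + h + 1, c - h : c + h + 1]
        if sub.shape != (min_roi_window, min_roi_window) or not sub.all():
            raise GeometryError(f"{name} mask smaller than the ROI window")

    rng = np.random.default_rng(params.seed)
    dt = 1000.0 / params.sample_rate_hz
    n = int(round(params.duration_s * 1000.0 / dt))
    a_rise, a_act, v_rise, v_act = _schedule(params, rng)
    sig_a = _render(a_rise, params.waveform("atrium"), n, dt)
    sig_v = _render(v_rise, params.waveform("ventricle"), n, dt)

    t_s = np.arange(n) * dt / 1000.0
    drift_phase = rng.uniform(0, 2 * math.pi)
    drift = params.drift_amplitude * np.sin(
        2 * math.pi * t_s / params.drift_period_s + drift_phase
    )
    sign = -1.0 if params.polarity == "negative" else 1.0
    lvl_a = _CAMERA_OFFSET + _CAMERA_GAIN * (sign * sig_a + drift)
    lvl_v = _CAMERA_OFFSET + _CAMERA_GAIN * (sign * sig_v + drift)
    lvl_bg = _CAMERA_OFFSET + _CAMERA_GAIN * drift

    H, W = geometry.grid
    out = np.empty((n, H, W), dtype=np.uint16)
    noise_counts = params.noise_sd * _CAMERA_GAIN
    chunk = max(1, int(2e7 // (H * W)))
    for i0 in range(0, n, chunk):
        i1 = min(n, i0 + chunk)
        block = np.broadcast_to(lvl_bg[i0:i1, None, None], (i1 - i0, H, W)).copy()
        block[:, mask_a] = lvl_a[i0:i1, None]
        block[:, mask_v] = lvl_v[i0:i1, None]
        if noise_counts:
            block = block + rng.normal(0.0, noise_counts, block.shape)
        np.clip(block, 0, 65535, out=block)
        out[i0:i1] = np.round(block).astype(np.uint16)

    stack = FrameStack(out, params.sample_rate_hz, params.modality)
    return stack, _ground_truth(params, a_act, v_act)


__all__ = [
    "WaveformShape",
    "WaveformTemplate",
    "ConductionPattern",
    "SimParams",
    "GroundTruth",
    "ChamberGeometry",
    "make_waveform",
    "simulate_recording",
    "simulate_framestack",
    "chain_reference_upstroke",
    "chain_references",
    "ANALYSIS_CUTOFF_HZ",
]
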