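"""Beat detection and per-beat feature estimators."""

import math
from dataclasses import replace

import numpy as np
import pytest

from cardiomap import features as ft
from cardiomap import preprocess as pp
from cardiomap.containers import BeatWindow, Trace
from cardiomap.errors import (
    InsufficientBeatsError,
    NoRhythmError,
    OrderingError,
    UnterminatedBeatError,
)
from cardiomap.synth import WaveformShape, make_waveform, simulate_recording


def ramp_beat(rise_ms, decay_ms, fs=500.0, pre_ms=100.0, decay_model="linear"):
    """A single normalized beat with leading baseline, as a Trace plus its
    BeatWindow."""
    shape = WaveformShape(rise_ms, decay_model, decay_ms)
    tmpl = make_waveform(shape, fs).samples
    pre = int(pre_ms * fs / 1000.0)
    x = np.concatenate([np.zeros(pre), tmpl, np.zeros(pre)])
    tr = Trace(x, fs)
    peak = pre + int(np.argmax(tmpl))
    return tr, BeatWindow(pre, peak, x.size)


class TestDetectBeats:
    def test_clean_240bpm_ten_seconds_counts(self, clean_params):
        params = replace(clean_params, atrial_rate_bpm=240.0)
        tr, _, _ = simulate_recording(params)
        wins = ft.detect_beats(pp.temporal_lowpass(tr))
        assert abs(len(wins) - 40) <= 1

    def test_single_beat_no_rhythm(self):
        tr, _ = ramp_beat(10.0, 100.0)
        with pytest.raises(NoRhythmError):
            ft.detect_beats(tr)

    def test_noisy_detection_matches_true_count(self, wt_params):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            tr, _, gt = simulate_recording(replace(wt_params, seed=seed))
            wins = ft.detect_beats(pp.temporal_lowpass(tr))
            # complete windows may lose one boundary beat
            if abs(len(wins) - len(gt.atrial_activation_times_ms)) <= 1:
                hits += 1
        assert hits >= 0.95 * n_seeds


class TestHeartRate:
    def test_uniform_intervals(self):
        peaks = np.arange(11) * 250.0
        per, mean, sem = ft.heart_rate(peaks)
        assert mean == pytest.approx(240.0)
        assert sem == pytest.approx(0.0, abs=1e-9)

    def test_three_peaks(self):
        _, mean, _ = ft.heart_rate([0.0, 300.0, 600.0])
        assert mean == pytest.approx(200.0)

    def test_non_monotonic_rejected(self):
        with pytest.raises(OrderingError):
            ft.heart_rate([0.0, 300.0, 200.0])


class TestActivation:
    @pytest.mark.parametrize("rise_ms, expected", [(10.0, 100.0), (50.0, 20.0)])
    def test_linear_rise_slope(self, rise_ms, expected):
        tr, w = ramp_beat(rise_ms, 150.0, fs=1000.0)
        act = ft.activation(tr, w)
        assert act.slope == pytest.approx(expected, rel=1e-6)

    def test_ramp_activation_at_midpoint(self):
        tr, w = ramp_beat(20.0, 150.0, fs=1000.0)
        act = ft.activation(tr, w)
        # window onset is at the start of the 100 ms lead-in ramp base
        assert act.time_ms - w.onset * tr.dt_ms == pytest.approx(10.0, abs=tr.dt_ms)

    def test_half_sine_upstroke_slope(self):
        fs, T = 10000.0, 40.0  # ms
        t = np.arange(int(fs * 0.4)) * 1000.0 / fs
        y = np.zeros_like(t)
        rise = (t >= 50.0) & (t < 50.0 + T)
        y[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - 50.0) / T))
        y[t >= 50.0 + T] = np.clip(1 - (t[t >= 50.0 + T] - 50.0 - T) / 200.0, 0, 1)
        tr = Trace(y, fs)
        w = BeatWindow(int(50 * fs / 1000), int((50 + T) * fs / 1000), y.size)
        act = ft.activation(tr, w)
        analytic = math.pi / (2 * T * 1e-3)
        assert act.slope == pytest.approx(analytic, rel=1e-3)
        # maximum slope of a half-sine rise is at its midpoint
        assert act.time_ms == pytest.approx(50.0 + T / 2, abs=0.2)

    def test_units_scale_inverse_with_rise_time(self):
        for rise in (5.0, 12.5, 80.0):
            tr, w = ramp_beat(rise, 200.0, fs=2000.0)
            act = ft.activation(tr, w)
            assert act.slope == pytest.approx(1000.0 / rise, rel=1e-6)


class TestDuration80:
    @pytest.mark.parametrize(
        "rise, decay, model, expected",
        [
            (0.0, 100.0, "linear", 80.0),
            (10.0, 100.0, "linear", 85.0),
            (0.0, 50.0, "exponential", 50.0 * math.log(5.0)),
        ],
    )
    def test_closed_form_cases(self, rise, decay, model, expected):
        tr, w = ramp_beat(rise, decay, fs=10000.0, decay_model=model)
        act = ft.activation(tr, w)
        d80 = ft.duration80(tr, act, w)
        assert d80 == pytest.approx(expected, rel=5e-3)

    def test_unterminated_beat_rejected(self):
        tr, w = ramp_beat(10.0, 100.0, fs=500.0)
        short = BeatWindow(w.onset, w.peak, w.peak + 5)
        act = ft.activation(tr, short)
        with pytest.raises(UnterminatedBeatError):
            ft.duration80(tr, act, short)

    def test_longer_decay_never_shortens_duration(self):
        prev = 0.0
        for decay in (60.0, 90.0, 130.0, 200.0):
            tr, w = ramp_beat(12.0, decay, fs=2000.0)
            act = ft.activation(tr, w)
            d80 = ft.duration80(tr, act, w)
            assert d80 > prev
            prev = d80


class TestSummarizeBeats:
    def test_identical_beats_zero_sem(self):
        bf = ft.summarize_beats(
            np.full(10, 240.0), np.full(10, 20.0), np.full(10, 150.0),
            modality="Vm", chamber="atrium",
        )
        assert bf.summary["upstroke_speed"] == (20.0, 0.0)

    def test_one_to_ten_sem(self):
        vals = np.arange(1.0, 11.0)
        bf = ft.summarize_beats(
            vals, vals, vals, modality="Ca", chamber="ventricle"
        )
        mean, sem = bf.summary["duration80_ms"]
        assert mean == pytest.approx(5.5)
        assert sem == pytest.approx(np.std(vals, ddof=1) / np.sqrt(10), rel=1e-12)
        assert sem == pytest.approx(0.9574, abs=2e-4)

    def test_insufficient_beats_rejected(self):
        nine = np.arange(9.0)
        with pytest.raises(InsufficientBeatsError):
            ft.summarize_beats(nine, nine, nine, modality="Vm", chamber="atrium")


class TestSignalAverage:
    def _beats(self, params):
        tr, _, _ = simulate_recording(params)
        filt = pp.temporal_lowpass(tr)
        wins = ft.detect_beats(filt)
        norm = pp.normalize(filt, wins)
        acts = [ft.activation(norm, w) for w in wins]
        return norm, wins, acts

    def test_identical_beats_average_equals_single_beat(self, clean_params):
        norm, wins, acts = self._beats(clean_params)
        sel = slice(1, 11)
        avg = ft.signal_average(norm, wins[sel], acts[sel])
        act_avg, d80_avg = ft.features_from_average(avg)
        per_d80 = [ft.duration80(norm, a, w) for w, a in zip(wins[sel], acts[sel])]
        assert d80_avg == pytest.approx(np.mean(per_d80), abs=norm.dt_ms)
        per_slope = [a.slope for a in acts[sel]]
        assert act_avg.slope == pytest.approx(np.mean(per_slope), rel=1e-2)

    def test_noise_reduced_by_sqrt_n(self, clean_params):
        rng = np.random.default_rng(11)
        base, wins, acts = self._beats(clean_params)
        sigma = 0.02
        resid = []
        for _ in range(3):
            noisy = base.with_values(base.values + rng.normal(0, sigma, base.n_samples))
            avg = ft.signal_average(noisy, wins[1:11], acts[1:11])
            clean_avg = ft.signal_average(base, wins[1:11], acts[1:11])
            resid.append(np.std(avg.values - clean_avg.values))
        assert np.mean(resid) == pytest.approx(sigma / np.sqrt(10), rel=0.25)

    def test_alternating_durations_average_between(self):
        fs = 500.0
        short = make_waveform(WaveformShape(10.0, "linear", 100.0), fs).samples
        long = make_waveform(WaveformShape(10.0, "linear", 150.0), fs).samples
        cycle = int(0.4 * fs)
        x = np.zeros(12 * cycle)
        for i in range(10):
            tmpl = short if i % 2 == 0 else long
            start = (i + 1) * cycle
            x[start : start + tmpl.size] += tmpl
        tr = Trace(x, fs)
        wins = ft.detect_beats(tr)
        norm = pp.normalize(tr, wins)
        acts = [ft.activation(norm, w) for w in wins]
        avg = ft.signal_average(norm, wins, acts)
        _, d80_avg = ft.features_from_average(avg)
        d80_short = 5.0 + 80.0
        d80_long = 5.0 + 120.0
        assert d80_short < d80_avg < d80_long
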