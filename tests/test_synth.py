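"""Synthetic-recording generator: closed forms, schedules, determinism."""

import math
from dataclasses import replace

import numpy as np
import pytest

from cardiomap.errors import (
    GeometryError,
    InsufficientDurationError,
    InvalidShapeError,
    PresetLookupError,
)
from cardiomap.presets import cohort_preset, preset_expectations, preset_labels
from cardiomap.synth import (
    ChamberGeometry,
    ConductionPattern,
    SimParams,
    WaveformShape,
    make_waveform,
    simulate_framestack,
    simulate_recording,
)


def brute_force_features(shape: WaveformShape, fs: float = 10000.0):
    """Independent oracle: dense sampling, finite differences, root
    finding on the sampled template (midpoint of the earliest tied run
    for the activation point)."""
    t = make_waveform(shape, fs)
    y = t.samples
    d = np.gradient(y, 1.0 / fs)
    pk = int(np.argmax(y))
    dmax = d[: pk + 1].max()
    run = np.flatnonzero(d[: pk + 1] >= dmax * (1 - 1e-9))
    first = last = run[0]
    members = set(run.tolist())
    while last + 1 in members:
        last += 1
    iact = (first + last) / 2.0
    post = y[pk:]
    below = np.flatnonzero(post < 0.2)
    below = below[below > 0]
    i = int(below[0])
    x0, x1 = post[i - 1], post[i]
    t80_ms = (pk + i - 1 + (x0 - 0.2) / (x0 - x1)) * 1000.0 / fs
    return float(dmax), float(t80_ms - iact * 1000.0 / fs)


class TestMakeWaveform:
    @pytest.mark.parametrize(
        "shape, exp_slope, exp_d80",
        [
            # linear 10 ms rise, 100 ms decay: slope 1000/10, activation at
            # the ramp midpoint so duration80 = 5 + 0.8*100
            (WaveformShape(10.0, "linear", 100.0), 100.0, 85.0),
            # one-sample rise, linear decay: 80 % of the decay time
            (WaveformShape(0.0, "linear", 100.0), None, 80.0),
            # one-sample rise, exponential tau = 50: decline to 0.2 at tau ln 5
            (WaveformShape(0.0, "exponential", 50.0), None, 50.0 * math.log(5.0)),
            (
                WaveformShape(20.0, "plateau_then_linear", 80.0, plateau_ms=30.0),
                50.0,
                10.0 + 30.0 + 64.0,
            ),
        ],
    )
    def test_closed_forms_match_brute_force(self, shape, exp_slope, exp_d80):
        tmpl = make_waveform(shape, 10000.0)
        if exp_slope is not None:
            assert tmpl.max_slope == pytest.approx(exp_slope, rel=1e-9)
        assert tmpl.duration80_ms == pytest.approx(exp_d80, rel=1e-9)
        brute_slope, brute_d80 = brute_force_features(shape)
        if exp_slope is not None:
            assert brute_slope == pytest.approx(tmpl.max_slope, rel=5e-3)
        assert brute_d80 == pytest.approx(tmpl.duration80_ms, rel=5e-3)

    def test_template_starts_and_ends_at_zero_peaks_at_one(self):
        for shape in (
            WaveformShape(15.0, "linear", 120.0, rise_edge_ms=4.0, decay_edge_ms=4.0),
            WaveformShape(30.0, "exponential", 40.0, plateau_ms=20.0),
            WaveformShape(40.0, "plateau_then_linear", 60.0, plateau_ms=50.0,
                          rise_edge_ms=6.0, rise_bump=0.2, rise_bump_width_ms=16.0),
        ):
            tmpl = make_waveform(shape, 500.0)
            assert tmpl.samples[0] == 0.0
            assert tmpl.samples[-1] == 0.0
            # a pointy apex can fall between samples at 500 Hz
            assert tmpl.samples.max() == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(upstroke_ms=-1.0),
            dict(upstroke_ms=10.0, decay_ms=0.0),
            dict(upstroke_ms=10.0, decay_ms=-5.0),
            dict(upstroke_ms=10.0, plateau_ms=-1.0),
            dict(upstroke_ms=10.0, rise_edge_ms=6.0),  # edge > half rise
            dict(upstroke_ms=20.0, rise_bump=0.2),  # bump without width
        ],
    )
    def test_invalid_shapes_rejected(self, kwargs):
        with pytest.raises(InvalidShapeError):
            WaveformShape(**kwargs)


class TestSimulateRecording:
    def test_noiseless_one_to_one_delay_exact(self, clean_params):
        params = replace(
            clean_params,
            atrial_rate_bpm=240.0,
            conduction=ConductionPattern(av_delay_ms=70.0),
        )
        _, _, gt = simulate_recording(params)
        a, v = gt.atrial_activation_times_ms, gt.ventricular_activation_times_ms
        assert len(a) == len(v)
        np.testing.assert_allclose(v - a, 70.0, atol=1e-9)

    def test_two_to_one_counts(self, clean_params):
        params = replace(
            clean_params,
            atrial_rate_bpm=120.0,
            conduction=ConductionPattern(2, 1, av_delay_ms=70.0),
        )
        _, _, gt = simulate_recording(params)
        assert len(gt.atrial_activation_times_ms) == 20
        assert len(gt.ventricular_activation_times_ms) == 10

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_conduction_bookkeeping(self, k):
        cond = ConductionPattern(k, 1)
        n = 23
        assert cond.conducted(n).sum() == (n + k - 1) // k

    def test_same_seed_bit_identical(self, wt_params):
        a1, v1, _ = simulate_recording(wt_params)
        a2, v2, _ = simulate_recording(wt_params)
        np.testing.assert_array_equal(a1.values, a2.values)
        np.testing.assert_array_equal(v1.values, v2.values)

    def test_different_seed_differs(self, wt_params):
        a1, _, _ = simulate_recording(wt_params)
        a2, _, _ = simulate_recording(replace(wt_params, seed=wt_params.seed + 1))
        assert not np.array_equal(a1.values, a2.values)

    def test_insufficient_duration_rejected(self, wt_params):
        with pytest.raises(InsufficientDurationError):
            replace(wt_params, duration_s=2.0)

    def test_negative_polarity_inverts_signal(self, clean_params):
        pos, _, _ = simulate_recording(clean_params)
        neg, _, _ = simulate_recording(replace(clean_params, polarity="negative"))
        np.testing.assert_allclose(neg.values, -pos.values, atol=1e-12)


class TestSimulateFramestack:
    def test_roi_mean_equals_chamber_trace(self, clean_params, small_geometry):
        stack, _ = simulate_framestack(clean_params, small_geometry)
        tr_a, _, _ = simulate_recording(clean_params)
        r, c = small_geometry.roi_center("atrium")
        roi = stack.intensities[:, r - 2 : r + 3, c - 2 : c + 3].mean(axis=(1, 2))
        # intensity-scaled copy of the chamber trace (16-bit quantization)
        norm = (roi - roi.min()) / (roi.max() - roi.min())
        ref = (tr_a.values - tr_a.values.min()) / np.ptp(tr_a.values)
        assert np.abs(norm - ref).max() < 1e-3

    def test_overlapping_masks_rejected(self):
        geom = ChamberGeometry(
            grid=(64, 64),
            atrium_center=(32.0, 28.0),
            atrium_axes=(12.0, 12.0),
            ventricle_center=(32.0, 40.0),
            ventricle_axes=(12.0, 12.0),
        )
        with pytest.raises(GeometryError):
            geom.masks()

    def test_stack_determinism(self, wt_params, small_geometry):
        s1, _ = simulate_framestack(wt_params, small_geometry)
        s2, _ = simulate_framestack(wt_params, small_geometry)
        np.testing.assert_array_equal(s1.intensities, s2.intensities)


class TestCohortPresets:
    def test_wt_larva_expectations(self):
        gt = simulate_recording(cohort_preset("WT", "no-phenotype", "larva", "Vm"))[2]
        assert gt.hr_bpm["atrium"] == 244.0
        assert gt.av_delay_ms == 70.0

    def test_s191f_iso_atrial_apd80(self):
        gt = simulate_recording(
            cohort_preset("S191F", "phenotype+ISO", "larva", "Vm")
        )[2]
        assert gt.duration80_ms["atrium"] == pytest.approx(128.0, abs=0.5)

    def test_wt_adult_av_delay(self):
        params = cohort_preset("WT", "pre-ISO", "adult", "Vm")
        assert params.conduction.av_delay_ms == 50.1
        assert params.atrial_rate_bpm == 120.0  # 2 Hz pacing

    def test_ground_truth_matches_table_where_measurable(self):
        """Chain-measurable preset ground truths equal the tabulated
        means; upstrokes above the filter's response ceiling clamp."""
        for genotype, condition in preset_labels("larva"):
            exp = preset_expectations(genotype, condition, "larva")
            for mod in ("Vm", "Ca"):
                gt = simulate_recording(
                    cohort_preset(genotype, condition, "larva", mod)
                )[2]
                for chamber in ("atrium", "ventricle"):
                    up, d80 = exp[mod][chamber]
                    assert gt.duration80_ms[chamber] == pytest.approx(d80, abs=1.0)
                    assert gt.upstroke_speed[chamber] == pytest.approx(up, rel=0.05)

    def test_unknown_label_raises(self):
        with pytest.raises(PresetLookupError):
            cohort_preset("WT", "nonsense", "larva")
        with pytest.raises(PresetLookupError):
            cohort_preset("WT", "no-phenotype", "embryo")

    def test_seed_is_mandatory(self, wt_params):
        with pytest.raises(Exception):
            SimParams(
                atrial_rate_bpm=240.0,
                atrium_vm=wt_params.atrium_vm,
                ventricle_vm=wt_params.ventricle_vm,
                atrium_ca=wt_params.atrium_ca,
                ventricle_ca=wt_params.ventricle_ca,
                seed=None,
            )
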