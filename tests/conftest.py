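"""Shared fixtures: preset-derived simulation parameters and a small
camera geometry so frame-stack tests stay fast."""

from __future__ import annotations

from dataclasses import replace

import pytest

from cardiomap.containers import ROISpec
from cardiomap.presets import cohort_preset
from cardiomap.synth import ChamberGeometry


@pytest.fixture(scope="session")
def wt_params():
    """WT larval Vm preset (noise and jitter as in the study conditions)."""
    return cohort_preset("WT", "no-phenotype", "larva", "Vm", seed=1)


@pytest.fixture(scope="session")
def clean_params(wt_params):
    """Noise-free, jitter-free, drift-free variant for exactness tests."""
    return replace(
        wt_params,
        noise_sd=0.0,
        drift_amplitude=0.0,
        conduction=replace(wt_params.conduction, av_delay_jitter_ms=0.0),
    )


@pytest.fixture(scope="session")
def small_geometry():
    return ChamberGeometry.default_for_grid((48, 48))


@pytest.fixture(scope="session")
def small_rois(small_geometry):
    return [
        ROISpec(small_geometry.roi_center("atrium"), 5, "atrium"),
        ROISpec(small_geometry.roi_center("ventricle"), 5, "ventricle"),
    ]
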