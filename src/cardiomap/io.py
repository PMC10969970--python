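"""File formats and run configuration.

Recordings are multi-page 16-bit TIFF frame stacks or trace CSVs
(``time_s`` column plus one column per chamber); ground truth and reports
travel as JSON sidecars.  Frame/sample rates come from the run
configuration — camera file metadata is unreliable — and a mismatch
between configuration and a CSV's time column is a hard error.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import FrameStack, Modality, Polarity, ROISpec, Trace
from .errors import ConfigError, FormatError
from .pipeline import AnalysisSettings
from .synth import GroundTruth


def write_traces_csv(path, traces: list[Trace]) -> None:
    """Write traces as CSV with a ``time_s`` column plus one column per
    chamber.  All traces must share the sample rate and length."""
    if not traces:
        raise FormatError("no traces to write")
    rates = {t.sample_rate for t in traces}
    lengths = {t.n_samples for t in traces}
    if len(rates) != 1 or len(lengths) != 1:
        raise FormatError("traces must share sample rate and length")
    df = pd.DataFrame({"time_s": traces[0].times_ms / 1000.0})
    for t in traces:
        df[t.chamber] = t.values
    df.to_csv(path, index=False)


def read_traces_csv(
    path,
    modality: Modality = "Vm",
    polarity: dict[str, Polarity] | None = None,
    expected_rate_hz: float | None = None,
) -> list[Trace]:
    """Read a trace CSV (``time_s`` + named chamber columns).

    The sample rate is inferred from the time column and must be uniform;
    if ``expected_rate_hz`` is given a >0.1 % mismatch is a hard error.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing time_s column")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: fewer than 2 samples")
    dt = np.diff(t)
    if dt.min() <= 0 or (dt.max() - dt.min()) > 1e-6 * dt.mean() + 1e-12:
        raise FormatError(f"{path}: time column is not uniformly increasing")
    rate = 1.0 / float(dt.mean())
    if expected_rate_hz is not None and abs(rate - expected_rate_hz) > 1e-3 * expected_rate_hz:
        raise FormatError(
            f"{path}: sample rate {rate:.3f} Hz does not match configured "
            f"{expected_rate_hz} Hz"
        )
    polarity = polarity or {}
    out = []
    for col in df.columns:
        if col == "time_s":
            continue
        chamber = col if col in ("atrium", "ventricle") else "atrium"
        out.append(
            Trace(
                df[col].to_numpy(dtype=float),
                rate,
                chamber,  # type: ignore[arg-type]
                modality,
                polarity.get(col, "positive"),
            )
        )
    if not out:
        raise FormatError(f"{path}: no signal columns")
    return out


def write_framestack_tiff(path, stack: FrameStack) -> None:
    """Write a frame stack as a multi-page 16-bit TIFF."""
    data = stack.intensities
    if data.dtype != np.uint16:
        data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")


def read_framestack_tiff(path, frame_rate: float, modality: Modality = "Vm") -> FrameStack:
    """Read a multi-page TIFF as a frame stack.  The frame rate must be
    supplied (configuration), not trusted from file tags."""
    try:
        data = tifffile.imread(path)
    except Exception as e:  # noqa: BLE001 - normalize third-party errors
        raise FormatError(f"{path}: unreadable TIFF ({e})") from e
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3 or data.dtype == object:
        raise FormatError(f"{path}: not a constant-frame-size multi-page stack")
    return FrameStack(data, frame_rate, modality)


def write_ground_truth(path, gt: GroundTruth) -> None:
    Path(path).write_text(json.dumps(gt.to_dict(), indent=2))


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RecordingSpec:
    """One recording entry in a run configuration."""

    path: str
    label: str = ""
    rois: list[dict] = field(default_factory=list)
    polarity: dict[str, str] = field(default_factory=dict)

    def roi_specs(self) -> list[ROISpec]:
        out = []
        for r in self.rois:
            out.append(
                ROISpec(
                    center=tuple(r["center"]),
                    window=int(r.get("window", 5)),
                    chamber=r.get("chamber", "atrium"),
                )
            )
        return out


@dataclass
class RunConfig:
    """Validated run configuration for a batch analysis."""

    stage: str = "larva"
    modality: Modality = "Vm"
    sample_rate_hz: float = 500.0
    recordings: list[RecordingSpec] = field(default_factory=list)
    settings: AnalysisSettings = field(default_factory=AnalysisSettings)
    output_dir: str = "."
    seed: int | None = None

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        try:
            raw = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as e:
            raise ConfigError(f"cannot read config {path}: {e}") from e
        if raw.get("stage") not in ("larva", "adult"):
            raise ConfigError("config must set stage to 'larva' or 'adult'")
        if raw.get("modality", "Vm") not in ("Vm", "Ca"):
            raise ConfigError("modality must be 'Vm' or 'Ca'")
        settings = AnalysisSettings(stage=raw["stage"])
        for k, v in raw.get("settings", {}).items():
            if not hasattr(settings, k):
                raise ConfigError(f"unknown analysis setting {k!r}")
            setattr(settings, k, v)
        recs = []
        for r in raw.get("recordings", []):
            if "path" not in r:
                raise ConfigError("every recording needs a path")
            recs.append(
                RecordingSpec(
                    path=r["path"],
                    label=r.get("label", Path(r["path"]).stem),
                    rois=r.get("rois", []),
                    polarity=r.get("polarity", {}),
                )
            )
        cfg = cls(
            stage=raw["stage"],
            modality=raw.get("modality", "Vm"),
            sample_rate_hz=float(raw.get("sample_rate_hz", 500.0)),
            recordings=recs,
            settings=settings,
            output_dir=raw.get("output_dir", "."),
            seed=raw.get("seed"),
        )
        for rec in cfg.recordings:
            if not Path(rec.path).exists():
                raise ConfigError(f"recording not found: {rec.path}")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "stage": self.stage,
                "modality": self.modality,
                "sample_rate_hz": self.sample_rate_hz,
                "recordings": [asdict(r) for r in self.recordings],
                "settings": asdict(self.settings),
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_framestack_tiff",
    "read_framestack_tiff",
    "write_ground_truth",
    "read_ground_truth",
    "RecordingSpec",
    "RunConfig",
]
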