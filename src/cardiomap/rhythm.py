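"""AV conduction analysis: pair atrial and ventricular activations,
compute per-beat AV delay, and classify the conduction ratio (2:1 AV
block detection).

Matching is greedy-causal: each atrial activation is matched to the
earliest subsequent unmatched ventricular activation within the lag
window.  Conduction is physiologically causal, so greedy matching is
deterministic and never crosses pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, NoConductionError, NoRhythmError


@dataclass
class AVPairing:
    """Matched atrial/ventricular activation pairs and the leftovers."""

    pairs: list[tuple[float, float]] = field(default_factory=list)
    unmatched_atrial: list[float] = field(default_factory=list)
    unmatched_ventricular: list[float] = field(default_factory=list)
    #: per atrial beat, in order: True if it conducted (was matched)
    conducted_mask: list[bool] = field(default_factory=list)

    @property
    def delays_ms(self) -> np.ndarray:
        return np.array([v - a for a, v in self.pairs])

    @property
    def n_atrial(self) -> int:
        return len(self.pairs) + len(self.unmatched_atrial)


@dataclass
class RhythmReport:
    """Conduction classification over an analysis window.

    ``conduction_ratio`` is the reduced atrial:ventricular integer pair;
    ``block_flag`` is set whenever the ratio differs from 1:1;
    ``pattern`` is ``"1:1"``, ``"2:1"`` (sustained alternation), ``"k:1"``
    for other exact ratios, or ``"irregular"`` for scattered dropout.
    """

    conduction_ratio: tuple[int, int]
    block_flag: bool
    pattern: str
    av_delay_mean_ms: float
    av_delay_sem_ms: float
    n_pairs: int


def pair_activations(
    atrial_times_ms,
    ventricular_times_ms,
    max_lag_ms: float | None = None,
) -> AVPairing:
    """Greedy-causal matching of atrial to ventricular activations.

    Each atrial activation takes the earliest subsequent ventricular
    activation within ``(0, max_lag_ms]`` that is not already matched.
    The default lag window is min(median atrial cycle length, 200 ms).
    """
    a = np.sort(np.asarray(atrial_times_ms, dtype=float))
    v = np.sort(np.asarray(ventricular_times_ms, dtype=float))
    if a.size == 0:
        raise NoRhythmError("no atrial activations")
    if max_lag_ms is None:
        cycle = float(np.median(np.diff(a))) if a.size > 1 else math.inf
        max_lag_ms = min(cycle, 200.0)

    pairing = AVPairing()
    j = 0
    for t_a in a:
        while j < v.size and v[j] <= t_a:
            pairing.unmatched_ventricular.append(float(v[j]))
            j += 1
        if j < v.size and v[j] - t_a <= max_lag_ms:
            pairing.pairs.append((float(t_a), float(v[j])))
            pairing.conducted_mask.append(True)
            j += 1
        else:
            pairing.unmatched_atrial.append(float(t_a))
            pairing.conducted_mask.append(False)
    pairing.unmatched_ventricular.extend(map(float, v[j:]))
    return pairing


def _is_periodic(mask: np.ndarray, k: int, threshold: float) -> bool:
    """True if at least ``threshold`` of the beats follow a strict
    one-conducted-per-k pattern (any phase)."""
    for phase in range(k):
        expect = np.arange(mask.size) % k == phase
        if (mask == expect).mean() >= threshold:
            return True
    return False


def conduction_ratio(
    pairing: AVPairing, alternation_threshold: float = 0.8
) -> RhythmReport:
    """Classify the conduction ratio over the analysis window.

    Unmatched atrial beats at the window boundaries (before the first or
    after the last conducted beat) are trimmed first: beat detection
    discards partial boundary beats per chamber, so the two activation
    lists need not cover identical spans.  Within the core window,
    all-conducted is 1:1; a sustained one-per-k pattern covering at least
    ``alternation_threshold`` of the beats is k:1 block (2:1 requires the
    strict alternating conducted/dropped pattern); anything else —
    scattered dropout — is labelled ``irregular`` with the reduced count
    ratio and the block flag set.
    """
    n_a = pairing.n_atrial
    if n_a < 4:
        raise InsufficientDataError(f"only {n_a} atrial activations")
    delays = pairing.delays_ms
    n_pairs = delays.size
    mean = float(delays.mean()) if n_pairs else math.nan
    sem = float(delays.std(ddof=1) / np.sqrt(n_pairs)) if n_pairs > 1 else 0.0
    mask = np.asarray(pairing.conducted_mask, dtype=bool)
    if not mask.any():
        return RhythmReport((n_a, 0), True, "no-conduction", mean, sem, 0)
    first, last = np.flatnonzero(mask)[[0, -1]]
    core = mask[first : last + 1]
    n_core, n_v = core.size, int(core.sum())
    if core.all():
        return RhythmReport((1, 1), False, "1:1", mean, sem, n_pairs)
    for k in (2, 3, 4):
        if _is_periodic(core, k, alternation_threshold):
            return RhythmReport((k, 1), True, f"{k}:1", mean, sem, n_pairs)
    g = math.gcd(n_core, n_v)
    return RhythmReport(
        (n_core // g, n_v // g), True, "irregular", mean, sem, n_pairs
    )


def av_delay_summary(pairing: AVPairing) -> tuple[float, float, np.ndarray]:
    """Mean +/- SEM AV delay over matched pairs, plus the per-beat list."""
    delays = pairing.delays_ms
    if delays.size == 0:
        raise NoConductionError("no matched atrial-ventricular pairs")
    sem = float(delays.std(ddof=1) / np.sqrt(delays.size)) if delays.size > 1 else 0.0
    return float(delays.mean()), sem, delays


__all__ = [
    "AVPairing",
    "RhythmReport",
    "pair_activations",
    "conduction_ratio",
    "av_delay_summary",
]
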