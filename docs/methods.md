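# Methods

`cardiomap` measures beat-level cardiac electrophysiology from dual-chamber
fluorescence recordings — membrane voltage (V_m, a voltage-sensitive
indicator) or intracellular calcium (Ca²⁺, a calcium indicator) imaged over
the atrium and ventricle — and validates the whole measurement chain
against a synthetic-recording generator with known ground truth.

## The measurement chain

1. **Polarity correction.** A negative-polarity optical signal (fluorescence
   falls on depolarization) is inverted about its median.  Polarity is
   declared in configuration, never auto-detected: silent auto-inversion
   would corrupt every downstream feature.  An opt-in heuristic is not
   provided in this version.
2. **Spatial filtering (frame stacks).** Each frame is convolved with a
   5 × 5 uniform box (reflect padding), then a square ROI (5 × 5 pixels for
   larval recordings; 11 × 11 by default for adult hearts, with a literal
   10 × 10 even-window option anchored at the top-left of center) is
   averaged per frame to give one trace per chamber.
3. **Temporal filtering.** A 50 Hz low-pass Butterworth, 4th order, applied
   forward and backward (`filtfilt`, zero phase) so activation times are
   not delayed.  The effective magnitude response is the squared
   Butterworth response.
4. **Beat segmentation.** Peaks are found from upward crossings of 50 % of
   the robust amplitude (5th–95th percentile range) with a refractory
   period of 40 % of the running median cycle length.  The detected peak is
   refined to the midpoint of the contiguous top region (within 5 % of the
   beat maximum): on round-topped beats the raw argmax wanders across the
   whole top under noise, and because heart rate is the mean of
   60000/interval, symmetric interval jitter biases it upward (convexity).
   Beat windows run from each upstroke onset (walk-back to the 10 %
   amplitude level) to the next onset; partial boundary beats are
   discarded.  Threshold crossings that walk back to the same onset (noise
   re-crossings within one beat) are merged.
5. **Normalization.** Per beat, dF_n = (F − baseline)/(peak − baseline).
   The baseline is the median of the low-lying (below 15 % amplitude)
   portion of the diastolic interval ending 5 ms before the upstroke
   onset, restricted to its last 30 %; the first beat uses the leading
   segment.  A peak-to-baseline excursion below 5× the trace noise
   estimate (median absolute successive difference / (0.6745·√2)) raises a
   flat-signal error — the contract for an ROI placed on background.
6. **Per-beat features.**
   - *Activation*: the time and magnitude of max dF_n/dt, by central
     differences on the filtered normalized trace (no extra smoothing; the
     50 Hz filter already bounds derivative noise), computed strictly
     inside the beat window so per-beat scale steps at window boundaries
     cannot leak into the derivative.  When several samples tie at the
     maximum (a constant-slope ramp), the midpoint of the earliest tied
     run is used — for a pure ramp this is the ramp midpoint, which is
     also where the smoothed synthetic shapes peak after filtering.
   - *Upstroke speed*: that maximal slope, in 1/s (dF_n/dt_max).
   - *Duration at 80 % recovery* (APD80 for V_m, CaTD80 for Ca): from the
     activation point to the first post-peak crossing of dF_n = 0.2
     (peak = 1, rest = 0), located by linear interpolation between
     samples.  Beats that never recover inside their window are excluded
     and logged.
   - *Heart rate*: per-interval 60000/peak-to-peak (ms), summarized as the
     mean over the selected intervals.  Read from the atrial trace by
     default (configurable); under AV block the two chambers' rates are
     reported separately.
7. **Summaries.** Larval protocol: per-beat features over the first ten
   complete beats, mean ± SEM (sd/√n).  Adult protocol: the ten beats are
   signal-averaged by aligning their activation points on the native 2 ms
   grid (linear interpolation; pointwise mean where at least half the
   beats contribute), the average's peak is rescaled to 1 (its baseline is
   0 by construction of the per-beat normalization), and the features are
   measured on the averaged waveform.  Which ten beats the original
   protocol used is not specified; the first ten complete beats is the
   default and configurable.
8. **AV conduction.** Atrial and ventricular activations are matched
   greedy-causally: each atrial activation takes the earliest subsequent
   unmatched ventricular activation within (0, max_lag], with max_lag
   defaulting to min(median atrial cycle, 200 ms).  AV delay is the mean ±
   SEM over matched pairs.  Conduction classification trims unmatched
   atrial beats at the window edges (beat detection discards partial
   boundary beats per chamber, so the two lists need not span identical
   windows), then reports 1:1 if every core beat conducted, k:1 (k = 2–4)
   if at least 80 % of beats follow a strict one-conducted-per-k pattern
   (threshold configurable), and otherwise "irregular" with the reduced
   count ratio; the block flag is set whenever the pattern is not 1:1.
   The criterion by which a heart "develops" 2:1 block is this package's
   operationalization (sustained alternation), since no standard window is
   established.

## Cohort statistics

Group values are summarized as mean ± SEM grids (one column block per
group with n individuals and N clutches).  Comparisons use the
tie-corrected Kruskal–Wallis H with Dunn's post hoc z-tests,
Bonferroni-adjusted over the requested comparison set (the comparison set
is explicit configuration), or two-tailed Student's t-tests — pooled
variance for unpaired (a Welch option exists), with p = 1 by convention
for a paired test whose differences are all zero.  Incidence percentages
and fold-ratios are computed from unrounded fractions and rounded half-up
only at presentation precision (one decimal).  Survival-curve estimation
is out of scope: published per-clutch-weighted survival percentages are
not reproducible from pooled counts without the unstated weighting.

## The synthetic-data generator

The generator emulates the study's two recording protocols: in vivo
larval hearts beating spontaneously at ~230–260 bpm, imaged for 10 s at
500 frames/s, and ex vivo adult hearts paced at 2 Hz, with epochs of 6 s
so that at least eleven complete cycles exist for ten-beat analysis.
Atrial beats follow a strictly regular schedule; ventricular beats follow
the conduction pattern (k:1 ratios and/or Bernoulli dropout) after an AV
delay with truncated-Gaussian per-beat jitter (default sd 2 ms, floor
1 ms).  Additive white Gaussian noise (default pixel sd 0.05 in
peak-normalized units), sinusoidal baseline drift (amplitude 0.03, period
3 s), signal polarity, and a 16-bit camera model (offset 2000 counts,
gain 30000 counts, per-pixel i.i.d. noise, uint16 quantization, two
elliptical chamber masks on a 128 × 128 grid by default) complete the
forward model.  Motion artifact is deliberately absent (the emulated
protocols used excitation–contraction uncoupling), as are photon
(Poisson) statistics — the analysis chain is linear, so Gaussian noise
exercises the same paths — and FRET ratio imaging (single emission
channel).

### Waveform templates

A beat is a rise–plateau–decay template with analytically known features.
The rise and linear decay are piecewise-linear with cosine-smoothed
derivative edges; the closed forms reduce to the textbook expressions as
the edge widths go to zero: max slope 1000/Δt (1/s) for a Δt-ms ramp,
activation at the ramp midpoint, duration80 = (time from activation to
peak) + plateau + 0.8·D for a linear decay over D ms, and τ·ln 5 for an
exponential decay.  Two refinements were forced by filter physics, both
verified against dense-grid numerical oracles:

- **Smoothed edges.** A zero-phase Butterworth rings at slope
  discontinuities; with sharp corners the measured max slope is biased
  ~5–8 % and the apparent activation point sticks to the edge ring rather
  than the ramp midpoint, which would corrupt AV delays whenever the two
  chambers have unequal rise times.
- **A center slope bump.** Even with smoothed edges the filtered
  derivative of a flat-slope ramp is M-shaped (edge rings exceed the
  mid-section).  Preset shapes therefore carry a cosine-shaped +30 %
  excess slope over a 16 ms window at the rise midpoint, which keeps the
  filtered derivative unimodal and centered; the closed-form max slope
  accounts for it exactly.

### Preset calibration

`cohort_preset` returns generator parameters whose ground truth equals a
study group's published mean features (heart rate, AV delay, upstroke
speed, duration80, per chamber and modality, larval and adult).  Heart
rate and AV delay are schedule parameters and exact.  Waveform shapes are
solved in two nested root-finds against the *deterministic noiseless
measurement chain* (`chain_references`): the rise duration so the chain
reports the target upstroke speed, and the decay so the chain reports the
target duration80, iterated to a joint fixed point.  Shape support is
constrained to leave ≥ 14 ms of flat diastole per cycle so every beat
returns to baseline.

Calibration respects a hard physical limit: the 50 Hz zero-phase filter's
derivative response ceiling is ~2·f_c·∫dx/(1+x⁸) ≈ 103 1/s for
unit-amplitude waveforms, so upstroke speeds above roughly 85–100 1/s
(adult action potentials) are not measurable through this chain no matter
the template.  For those entries the template keeps the closed-form rise
and the ground truth records the chain reference — `GroundTruth` carries
both the chain-measurable values (`upstroke_speed`, `duration80_ms`) and
the raw template closed forms (`template_max_slope`,
`template_duration80_ms`).  Recovery tests compare against the
chain-measurable references, which equal the published means everywhere
the filter permits.

### What passing recovery shows — and what it does not

End-to-end recovery (frame stack → spatial filter → ROI → temporal filter
→ beats → features) at pixel noise sd 0.05 over 20 seeds demonstrates
that the chain is unbiased and precise under the generator's assumptions:
regular rhythm, homogeneous chambers, stationary Gaussian noise, no
motion.  Real recordings add motion residue, photobleaching beyond slow
drift, heterogeneous intra-chamber activation, and rate variability; the
tests bound estimator error, not robustness to those effects.  Note also
that at trace-level noise much above ~0.01 the max-of-derivative
statistic acquires an upward noise bias (an extreme-value effect);
the pixel-level 0.05 condition is measurable only because the spatial
box filter and ROI averaging reduce trace noise ~7-fold.

## Numerical choices

- Milliseconds internally, seconds in CSV time columns, 0-based half-open
  beat windows.
- Derivative-tie tolerance 1e-9 (relative); exponential templates
  truncated at 1e-4 of peak; flat-signal threshold 5× the noise estimate.
- Simulation problem sizes in the test suite: 48 × 48 pixel grids (masks
  scaled from the 128 × 128 default) and 6–20 seeds per check, chosen so
  the statistical tolerances are meaningfully exercised by the suite.
- Determinism: one `numpy` Generator seeded from `SimParams.seed` drives
  schedule jitter, dropout, drift phase and pixel noise in a fixed order;
  identical parameters give bit-identical recordings.

## Known limitations

- Adult AP upstroke speeds above the 50 Hz filter ceiling are reported as
  chain references, not the published means (see above); published adult
  values of ~100–150 1/s imply the original analysis used a leakier
  filter than any standard reading of "50 Hz low-pass Butterworth,
  zero-phase, 4th order".
- The box-filter-before-ROI order is one reading of the protocol; the
  alternative (ROI directly on unfiltered frames) is exposed via
  configuration (`spatial_first=False`) and is equivalent on
  homogeneous-chamber data.
- No conduction-velocity maps, alternans/restitution metrics, or
  Wenckebach subtyping; rhythm analysis is limited to AV conduction
  ratios.
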