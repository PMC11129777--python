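# Methods

`laminarid` implements laminar identification for cortical recordings made
with high-density linear probes (Neuropixels-class: two staggered columns,
~20 µm row pitch, hundreds of sites). Two independent markers are derived
per session and fused:

1. **Flash-evoked current source density (CSD).** The CSD along the probe is
   the negated second spatial derivative of the trial-averaged
   stimulus-evoked LFP, `C(z, t) = −∂²V/∂z²`, in arbitrary units — no tissue
   conductivity is applied because only the relative timing and location of
   sinks and sources matter for finding the input layer. The earliest
   mid-cortical sink marks the thalamorecipient input layer (layer 4).
2. **Spike–LFP phase reversal.** Per depth group of `group_size` channels,
   the mean LFP is band-pass filtered 5–35 Hz (zero-phase Butterworth),
   converted to instantaneous phase by the Hilbert transform, and sampled at
   every spike of every spike-depth group; each (spike group × LFP group)
   cell holds the circular mean phase. The depth at which the aggregate
   phase profile jumps by ~π marks the layer IV/V transition, just below the
   input-layer middle. The reversal, when present, is adopted as the IV/V
   boundary; the CSD sink serves as a consistency check.

## Model assumptions

- The LFP stream is already low-pass decimated (~1 kHz); wide-band (30 kHz)
  processing and spike sorting are upstream concerns (Kilosort/Phy output is
  read, not produced).
- Depths live on a canonical axis in µm: 0 at the most superficial channel,
  increasing toward the tip. Rows are equispaced at the probe pitch; the
  two columns of a row are electrically equivalent for laminar purposes and
  are averaged ("collapsed") before the spatial derivative.
- Channel order follows depth, so a 10-channel group spans 5 rows = 100 µm —
  which is why the chunked CSD resembles classic 100 µm probes.
- The spike–field analysis uses the first `analysis_minutes` of the session
  unconditionally (task epochs included); with a shorter recording all of it
  is used and a warning is emitted.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `band_lo_hz`, `band_hi_hz` | 5, 35 | Hz | spike–field analysis band |
| `filter_order` | 4 | poles | band-pass pole count (forward–backward) |
| `group_size` | 10 | channels | depth group for chunked CSD and phases |
| `smooth_window_ch/ms`, `smooth_sd` | 120, 20, 12 | channels, ms | dense-CSD Gaussian kernel |
| `chunk_smooth_*` | 3, 5, 1.1 | groups, ms | chunked-CSD Gaussian kernel |
| `analysis_minutes` | 15 | min | spike–field window |
| `min_spikes_per_cell` | 50 | — | mask high-variance circular means |
| `epoch_pre_s`, `epoch_post_s` | 0.25, 0.3 | s | peri-flash epoch and baseline |
| `threshold_k`, `sustain_ms` | 4.0, 5 | SD, ms | sink-onset criterion |
| `min_flip_rad` | π/2 | rad | reversal-report floor |
| `max_offset_um` | 300 | µm | CSD/reversal consistency tolerance |
| `l4_half_thickness_um` | 250 | µm | CSD-only boundary fallback |

## Numerical and design choices

**Gaussian kernel units.** The dense kernel "(120 channels, 20 ms, SD 12)"
is read in *channel* units and applied to the raw channels × time evoked
average *before* column collapse. On a two-column probe adjacent channels
step ~10 µm in depth, so SD 12 channels ≈ 120 µm — nearly identical to the
chunked path's SD of 1.1 groups ≈ 110 µm, which is exactly why the two
variants give nearly identical CSDs (we verify r ≥ 0.9). Reading the SD in
row units (240 µm) would suppress a dipole with sources ±300 µm from the
sink by ~25×, and makes the two variants visibly different; the channel-unit
reading is therefore adopted. A single SD is shared by both axes in native
units (channels; ms), with the stated windows as truncation lengths
(widened to odd length). Edges are handled by symmetric reflection.
All of this is configurable.

**Second difference.** `C[i] = −(V[i−1] − 2V[i] + V[i+1]) / h²` on interior
rows only (sink-negative); no extrapolated CSD at the probe ends. The
chunked path differentiates at the group-centre spacing (100 µm by
default). Display upsampling uses an exact bicubic spline
(`RectBivariateSpline`), which preserves the original grid nodes.

**Sink-onset detector.** The study located the earliest sink visually; a
reproducible operationalization is required. Per row, onset is the first
post-stimulus time the CSD stays below (baseline mean − `threshold_k` ×
baseline SD) for ≥ `sustain_ms`; the reported depth is the |CSD|-weighted
centroid of the contiguous sub-threshold region at the earliest row's
peak-sink time. With ~200 rows of band-limited residual noise a 2 SD floor
false-triggers almost surely (low-frequency noise stays on one side of the
threshold for tens of ms, defeating the sustain test), so the default is
`threshold_k = 4`; the planted sink in the simulations sits at |z| ≈ 50, so
the margin is wide on both sides. The pipeline runs the detector on the
chunk-path CSD: its 5 ms / SD 1.1 ms time kernel biases a threshold onset
by ≤ ~2.5 ms, whereas the 20 ms / SD 12 ms dense kernel can advance it by
up to ~10 ms.

**Phase sampling and binning.** Phases are sampled at the nearest LFP
sample (1 ms). At 35 Hz the worst-case error is < 0.11 rad, below every
tolerance used; a linear (phasor-interpolating) alternative is available
via `phase_sampling="linear"`. Circular means are computed from raw
(unbinned) phases: the circular mean of binned phases converges to the
unbinned mean, and an arbitrary bin width would otherwise leak into
results. The resultant length R accompanies every mean; a cell with
R < 1e-12 (e.g. antipodal input) is undefined and masked, not an error.

**Reversal detector.** Per LFP group, the aggregate phase is the
spike-count-weighted circular mean over spike groups of that column;
the reversal is the depth midpoint of the adjacent pair with maximal
circular distance, reported only when the distance reaches `min_flip_rad`
(default π/2). The magnitude is reported either way.

**Common-average reference.** Subtracting the across-channel mean is
idempotent and removes any signal shared by all channels exactly. The
spike-field stage applies it by default (`apply_car`), mirroring the
recording configuration that motivates it: with an in-brain tip reference,
every channel inherits the reference site's rhythm, which drags all depth
groups to a common phase and masks the flip until re-referenced.

## The synthetic generator

No raw recordings accompany the study, so `laminarid.synthetic` generates
ground-truthed sessions with the statistical structure the analysis
assumes:

- **Evoked dipole**: a Gaussian sink (SD `sink_width_um` = 150 µm) at
  `sink_depth_um` with flanking sources at ±2 SD, scaled so every time
  slice sums exactly to zero over depth; time course is an alpha function
  (τ = 20 ms) starting `sink_onset_s` = 40 ms after each flash. The planted
  CSD is integrated into an LFP profile by the exact discrete inverse of
  the second-difference operator, so the estimator has an analytic target;
  a volume-conductor forward model is deliberately out of scope.
- **Rhythm with a planted flip**: a 12 Hz oscillation (within the 5–35 Hz
  band) whose amplitude profile is `tanh((flip_depth − z)/40 µm)` — sign
  inversion below `flip_depth_um` with a 40 µm taper to avoid a
  discontinuity artifact. Its phase performs a slow random walk
  (2 rad²/s), decorrelating across the 5 s inter-trial interval; a
  perfectly periodic rhythm would be commensurate with the ITI, survive
  trial averaging, and contaminate the evoked CSD.
- **Noise**: pink (1/f amplitude) noise, correlated across rows with an
  exponential profile (length 100 µm) — white noise would make CSD
  recovery unrealistically easy — plus 5 µV independent per-channel noise.
- **Units**: 220 units (the scale of the study's per-session yields)
  uniform within ±1 mm of the input layer, lognormal rates (median 4 Hz),
  spiking as inhomogeneous Poisson with von Mises modulation (κ = 1.5)
  locked to the global rhythm's phase track. Because the *field* inverts
  below the flip while unit excitability follows the same global rhythm,
  a deep unit's preferred phase relative to its local LFP is offset by π —
  reproducing the measured phase-matrix geometry (flip along the LFP-depth
  axis, uniform along the unit-depth axis).
- **Reference artifact** (optional): a scaled copy of the rhythm added to
  every channel, emulating an in-brain reference.
- Amplitudes (oscillation 50 µV, evoked 150 µV, noise 25 µV) are fixed at
  values typical of cortical LFP; a single integer seed drives all
  randomness and identical seeds give bit-identical sessions. Export
  quantizes to int16 at 0.1 µV/bit.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: volume conduction and realistic dipole
mixing across layers, non-stationary rates and bursting, eye-movement and
task structure, drift of the probe, realistic spike waveforms (the AP band
is absent), and inter-areal differences in rhythm frequency or locking
strength. Recovery results certify the estimators against their own
statistical model, not against biology.

## Problem sizes

Generator defaults follow the study paradigm: 75 flashes (within the
reported 50–100), 5 s ITI, 384 channels at 20 µm pitch, 1 kHz. The batch
experiments in `laminarid.validation` (used by the tests and
`scripts/acceptance.py`) run 380 s sessions with a 6 min spike-field
window — the package's desk-scale configuration; the defaults on
`AnalysisConfig` (15 min) and `simulate_session` remain the paradigm
values. Recovery margins at desk scale are wide (sink depth error ≲ 10 µm
against a ±50 µm tolerance; flip magnitude within ~0.05 rad of π against
±0.3), so the shortened window does not sit near any decision boundary.

## Known limitations

- The sink detector assumes a single dominant early sink; when two sinks
  tie at onset the deeper/stronger one wins deterministically, and
  interpretation is left to the caller.
- The chunk-path depth grid is 100 µm; reversal depths are midpoints of
  adjacent group centres and so quantized to ~50 µm.
- The CSD is never conductivity-scaled; magnitudes are comparable within a
  session only.
- `estimate_laminar`'s CSD-only fallback adds an assumed half layer-IV
  thickness (250 µm) — a convention, not a measurement.
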