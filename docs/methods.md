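# Methods

This note documents the models, rule constants and numerical choices
behind `phonoseg`, and what the synthetic validation does and does not
establish.

## Signal model and preprocessing

The input is a paired single-channel ECG and PCG sampled simultaneously
at 1 kHz. Every rule constant below is tied to that 1-ms grid; the CLI
refuses other rates rather than silently resampling.

**ECG path.** Band-pass 10–35 Hz, the band holding the dominant QRS
energy, as a cascade of two 251-tap Hamming-windowed linear-phase FIR
stages (high-pass, then low-pass). Each stage delays exactly 125 samples,
so the cascade delay is 250 samples; alignment drops the first 250
samples of the filtered ECG and the last 250 of the PCG. The `firwin`
design cut-offs are pre-warped outward by 3 Hz (half the Hamming
transition width at 251 taps) so the nominal 10/35 Hz behave as pass-band
edges: the realised cascade has <0.3 dB ripple over 12–33 Hz, −55 dB at
0.5 Hz and −58 dB at 50 Hz.

**PCG path.** Band-pass 20–100 Hz, order-5 Chebyshev type I with 0.5 dB
pass-band ripple ("Chebyshev" unqualified conventionally means type I;
the small ripple limits in-band distortion). The filter runs forward and
backward (`sosfiltfilt`) for an exactly zero net phase: a symmetric burst
keeps its peak sample, which the timing measurements require. The record
is reflect-padded by the filter's settling length — computed from the
slowest pole (radius ≈0.991 → ≈2900 samples for a 1e-12 decay) — rather
than a fixed small multiple of the order; short padding leaks the 20-Hz
edge transient into the record and breaks the time-reversal symmetry the
zero-phase property promises. The 100-Hz upper edge also suppresses
murmurs, whose energy sits at 200–600 Hz.

## R-peak detection

Classical Pan–Tompkins on the band-passed ECG: five-point derivative
(`(1/8)(2x[n] + x[n−1] − x[n−3] − 2x[n−4])`), point-wise squaring, 150-ms
moving-window integration (≈ the normal QRS duration). Candidate pulses
are local maxima of the integrated signal separated by a 200-ms
refractory period; they are accepted against the running two-level
threshold `noise + 0.25·(signal − noise)` (signal/noise estimates updated
with the usual 1/8 gains), with a search-back pass at half threshold when
more than 1.66× the running mean RR elapses without a beat. Thresholds
initialise from the first 2 s.

Two deliberate choices where the chain is conventionally "modified":

- **Noise floor.** Candidates below 5× the record-median integrated
  signal are rejected. QRS pulses concentrate energy into a small duty
  cycle, so the median of the integrated signal is the diastolic baseline
  and genuine beats tower over it; band-limited structureless noise never
  rises far above its own median. This makes the detector silent on
  records with no cardiac content, which adaptive thresholds alone do not
  achieve (they are scale-free and will happily "detect" noise maxima).
- **Relocation.** Each accepted pulse is mapped to the ECG maximum within
  ±75 ms of the delay-corrected pulse peak, so reported indices are
  R-peaks, not integrator peaks.

A premature ventricular contraction presents as a wide low-frequency
deflection; the 10-Hz high-pass attenuates it by orders of magnitude and
the detector never sees it, so PVC cycles contribute no beats and no
sounds.

## Shannon-energy envelope

The filtered PCG is normalised to `max |x| = 1` and transformed by the
second-order Shannon energy `ES(i) = −(1/N) Σ x²·log x²` over an N = 20
sample window advanced one sample at a time, keeping the full 1-ms
resolution (a 50 %-overlap window, the usual choice for whole-sound
segmentation, would hide the intra-sound split). Conventions: natural
log (any base change is a constant factor that the subsequent
normalisation absorbs exactly — tested), `0·log 0 = 0`, centred window
`[i−N/2, i+N/2)` shrunk to the valid range at the record edges with the
`1/N` scale fixed.

A moving normalisation follows: at each sample subtract the mean and
divide by the standard deviation over a centred 1-s sliding window, then
clamp negatives to zero. This equalises slow signal-quality drift; a 2-s
window gives statistically indistinguishable timing (tested as: parameter
means within 1 ms, ≥95 % of sounds individually unmoved). Regions of zero
sliding std (no signal at all) map to zero.

**Amplitude-ceiling caveat.** The Shannon transform emphasises
medium-intensity samples and vanishes at `|x| = 1`. A sound whose
amplitude reaches the record's normalisation ceiling therefore has a
flattened envelope lobe whose peak can wander by up to ~half the
integration window (~10 ms). On real records the ceiling is set by the
loudest transient, so typical sounds sit well below it; the effect is
visible only on a record's few loudest beats.

## Detection and classification rules

1. Segments are maximal runs with envelope > 5 % of the global maximum.
2. Segments closer than 10 % of the mean RR interval are joined (an
   under-threshold split must not cut one sound in two).
3. Within each segment, the two components are the two tallest envelope
   peaks at least N samples apart, and the split is the deepest
   (plateau-aware) local minimum between them. On a clean two-lobe
   envelope this is exactly "the deepest interior minimum"; restricting
   the search to the inter-peak range keeps sub-threshold noise ripples
   on the segment skirts — which can dip below the genuine valley without
   separating anything — from capturing the split. A valley shallower
   than 5 % of the envelope maximum (the method's own amplitude
   resolution) does not count: the segment is kept as a single-component
   *degenerate* sound, the physically honest output for a pair closer
   than the 20-ms window.
4. False-positive pruning on first components: of two closer than 20 % of
   the mean RR, the lower-envelope one is dropped; when two consecutive
   gaps are both under 40 %, the weakest of the triple is dropped;
   applied iteratively to stability.
5. Classification relative to the reference R-peak (nearest preceding, or
   following when the sound leads it by ≤50 ms): S1 when the first
   component lies in `[R − 50 ms, R + 0.18·RR]` (labels mitral,
   tricuspid); S2 when it lies beyond `R + 0.18·RR` *and the sound ends
   before the next beat's S1 window opens* (labels aortic, pulmonary).
   The upper S2 bound uses the sound's second component: a lone lobe just
   before the next R-peak belongs to no window and is discarded. At most
   one S1 and one S2 survive per cycle (highest envelope wins).

All ties (argmax/argmin, equal envelope) break to the earliest index, so
the pipeline is bit-for-bit deterministic.

## Timing parameters and validation metrics

Six per-beat parameters in ms: R–S1M, R–S1T, S1 split (= R–S1T − R–S1M),
R–S2A, R–S2P, S2 split. R–S1M may be negative (the S1 window opens 50 ms
before R). Degenerate sounds contribute *no* timing fields: their single
merged-lobe peak estimates the sound's position, not either component's,
and attributing it to the first component measurably biases the
statistics. Summaries report mean, std, median, IQR and the empirical
2.5–97.5 percentile range, with `n` per parameter.

**SNR.** `20·log10(AS / 4σ_N)`: `AS` is the peak-to-peak amplitude of the
R-peak-synchronous ensemble average over one mean cardiac cycle (mean RR
rounded to samples; incomplete trailing beats excluded); `σ_N` pools the
beat-aligned samples over 70–85 % of the cycle, a diastolic window where
no heart sound is expected (4σ spans the 95 % band of Gaussian noise).
Truly noiseless input returns an `inf` sentinel with a warning. The
measure is invariant to global amplitude scaling.

**Sensitivity / specificity.** Sensitivity takes the detected R-peaks as
the beat denominator: beats with a classified S1 (resp. S2) over beats,
×100; the overall figure is the mean of the two. Against synthetic ground
truth, a resolved sound only counts when both component estimates are
within ±10 ms of their true times (one true beat consumed per detection);
a degenerate sound counts when its single estimate lies within the true
sound's span ±10 ms — a merged estimate of an unresolvable pair
legitimately lands anywhere between the two true components.
Specificity is the fraction of detections that match a true sound.

## Synthetic data generator

The generator emulates the acquisition setting the method was designed
for; its defaults are the reference cohort means.

- **ECG**: piecewise-Gaussian P-QRS-T per beat (only the R location needs
  to be faithful); RR intervals jitter with σ = 25 ms around the
  programmed heart rate. PVCs replace a beat with a 40-ms-σ biphasic
  low-frequency wave and suppress that beat's sounds.
- **PCG**: per beat, four Gaussian-windowed 50-Hz tone bursts (duration
  40 ms ≈ ±2.5σ of the envelope) at delays drawn per beat as
  (first-component delay, split), each with its own jitter, the split
  clamped ≥2 ms so component order is invariant. Defaults: mitral
  43.9 ms, S1 split 32.1 ms, aortic 371.3 ms, S2 split 28.1 ms; jitters
  10/13/10/15 ms (the medians of the cohort's per-subject values).
  The burst carrier is phase-locked to the R-peak: real heart-sound
  waveforms are beat-synchronous, and without the lock the
  ensemble-average SNR numerator would collapse under timing jitter.
  Sound intensity varies per beat (lognormal σ = 0.2, plus σ = 0.05 per
  component), as it does physiologically with respiration — and without
  it every strongest lobe would sit exactly at the Shannon amplitude
  ceiling (see caveat above).
- **Noise**: white Gaussian shaped by the 262-Hz acquisition bandwidth.
  Its level is set by inverting the SNR definition deterministically:
  expected jitter-smeared mean beat waveform through the PCG band-pass
  for `AS`, frequency-response integral for the band-pass noise gain.
  Measured SNR lands within ~0.5 dB of target on 10-min records.
- **Murmur**: 200–490 Hz band-limited noise burst in systole (the 600-Hz
  textbook upper edge exceeds Nyquist at 1 kHz); the 20–100 Hz PCG filter
  removes it, which is what the specificity test verifies.
- **Cohort**: a built-in 24-subject table (heart rate 55–87 bpm, SNR
  12.5–33.7 dB floored at 13 dB, per-subject delays, splits and
  within-subject stds) drives `generate_cohort`; per-record seeds derive
  from one master seed.

**What a green cohort test establishes** — that the rule chain detects,
classifies and times tone-burst sounds with the published population's
timing structure at realistic SNR, with zero false sounds from murmurs,
noise or PVCs. **What it does not** — robustness to real-world artifacts
(motion, friction, speech), to morphology that is not a windowed tone
burst, to pathological rhythms beyond isolated PVCs, or to sensors and
bands other than the stated ones.

## Known limitations

- Splits below the 20-ms integration window are physically unresolvable
  by this envelope and are reported as degenerate single-component
  sounds; splits within ~25 % of the window resolve only on favourable
  beats, with an inward bias of a few ms near the limit.
- The loudest beats of a record suffer the amplitude-ceiling flattening
  (up to ~10 ms of peak wander on a noiseless record's ceiling beats).
- Sensitivity figures use detected R-peaks as the denominator; a missed
  R-peak (none observed on the synthetic cohort) would remove its beat
  from both numerator and denominator.
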