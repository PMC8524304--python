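# Methods

This note documents the models and procedures implemented in `platt`, the
choices made where the design was genuinely open, and what the synthetic
evaluation does and does not show.

## Signal model and processing chain

**Frequency decomposition.** The analysis filterbank consists of 78 complex
fourth-order Gammatone filters with center frequencies on a fixed Mel-spaced
grid (82 printed values from 64 to 15080 Hz; channels use grid positions
3–80, i.e. 123–13943 Hz, roughly 0.5 ERB apart).  Each filter is four
identical complex one-pole stages plus one complex feed-forward coefficient:
`H(z) = c / (1 − p z⁻¹)⁴`.  The pole phase is `2π f_c / f_s`.  The pole
radius is solved numerically (Brent root find) so that the fourth-order
magnitude response is −10 dB at `f_c ± bw/2`, where `bw` is the difference
of the grid frequencies two positions right and left of the center (e.g.
221 − 93 = 128 Hz for the 155 Hz channel).  The closed-form radius
expression in the source material is typographically corrupted; the
bandwidth condition itself is unambiguous, so the numeric solve is the
design definition here.  `|c|` normalizes the peak gain to 2; the phase of
`c` is set channel by channel (lowest channel = phase 0) so that each
neighboring pair agrees in phase at the delay where the product of their
temporal envelopes peaks, which minimizes destructive interference in the
summed output.

**Resynthesis.** The output is the real part of the sum of all band
signals.  Because neighboring peak-gain-2 filters overlap, the phase-aligned
sum is spectrally flat but not unity; a single scalar (`resynth_scale`,
measured at design time as the geometric-mean joint gain over 200 Hz–12 kHz)
restores unity gain so the dB SPL calibration survives the round trip.  The
measured joint response at 48 kHz is flat within ~0.3 dB over 200 Hz–12 kHz
and is a downward frequency sweep; the envelope-peak delay of the channel
nearest 2 kHz is ~2.0 ms and of the channel nearest 800 Hz ~3.7 ms (the
acceptance script recomputes both).  Per-channel gains are applied before
summation; their rate of change is clipped to 24 dB per period of the
channel's center frequency (zero-order hold from the 1 kHz frame rate, then
the per-sample slew limiter; the slew limiter alone defines the audible
contract, no smoother interpolator is used).

**Spectro-temporal representation.** Per channel, the instantaneous
amplitude is the magnitude of the complex band signal (the envelope of the
real-valued output; this avoids half-cycle ripple while holding the same
maxima).  A hold/decay automaton holds every new local maximum (ties
restart the hold) for 15 ms and then decays at 1 dB/ms until overtaken.
Onsets pass instantaneously; temporal fine structure is removed.  The
representation is decimated to 1000 frames/s — lossless for held maxima
since 15 ms ≫ 1 ms — converted to dB SPL (full-scale sine = 120 dB SPL by
default, `calibration_dbspl_fs`), and floored at the normal-hearing
threshold (ISO 226:2003 threshold-of-hearing table, vendored as a
(frequency, dB SPL) constant table with log-frequency linear interpolation,
clamped outside 20 Hz–12.5 kHz).

**Adaptive spectral gain.** Each 78-value frame is smoothed with unit-sum
Hanning windows of widths 8, 16, 32, 64 channels.  "Width n" is implemented
as the symmetric (n+1)-point Hanning (zero endpoints), whose FWHM is n/2
channels = n/4 ERB, matching the intended 2/4/8/16 ERB pattern sizes;
boundaries use reflection padding to avoid spurious edge roll-off of the
base layer.  The telescoping differences d1..d4 and the base layer (widest
smoothing) reconstruct the frame exactly.  The base layer is mapped
linearly between the input range (105 dB SPL top; bottom 25 dB SPL from
500 Hz–4 kHz and 30 dB SPL below 250 Hz / above 8 kHz, interpolated
linearly in log-frequency between the plateaus — the plateau transition is
a package choice, only the plateau values are fixed) and the output range,
or passed through (`identity`).  d1 and the (optionally expanded) `E·d2`
are added unconditionally and may exceed the output limits by design.  d3,
then d4, are added conditionally: per channel the largest factor in [0, 1]
that keeps the running output inside the output range (computed *after*
the expansion term, which is part of the current output dynamic), then the
strongest compression is spread with a peak-normalized Hanning taper
(w(0)=1, w(±FWHM/2)=0.5, w=0 beyond ±FWHM; FWHM 6 for d3, 12 for d4) via
`f_j = min_k (raw_k + 1 − w(j−k))`, single pass over all k.  This is the
only reading that reproduces the documented caps (raw 0 at 2708 Hz ⇒ ≤0.5
at 2346/3112 Hz, unaffected below 2023 and above 3565 Hz); note the
single-pass rule is not idempotent, and iterating it to a fixed point would
violate those caps.  The frame gain is desired output minus input frame.

The transparent configuration (identity base map, expansion 1, output range
equal to the input range) produces exactly zero gain for frames inside the
range; frames at the hearing floor (below the lower input limit) are still
manipulated, which is intended behavior of the compression management.

## Hearing-loss model (feature domain)

The recognition front end is a 36-channel log Mel-spectrogram (25 ms Hann,
10 ms shift, triangular filters with Mel-equidistant edges over
64–16000 Hz, Mel = 2595·log10(1 + f/700)), offset so that a tone at a
channel center reads its dB SPL level (windowing leakage adds ~1.8 dB when
pooling a tone's bins; broadband levels are consistent).  Class-D
manipulations act on this representation: an upper frequency limit removes
channels; *level uncertainty* adds i.i.d. Gaussian noise (SD `u` dB) to
every time–frequency value, freshly drawn per utterance from seeds derived
from a master seed, for training and testing features alike.  An optional
absolute-threshold audiogram (class A) floors values.  Composition order is
fixed: frequency limit → absolute threshold → level uncertainty.  Because
everything acts in the log domain, amplifying the audio by G dB shifts the
degraded features by exactly G — linear amplification cannot undo a class-D
manipulation.

## Synthetic signals

All evaluation inputs are generated, seeded and calibrated
(`level = 120 + 20·log10(rms·√2)` dB SPL):

* **Stationary speech-shaped noise** — Gaussian noise FFT-shaped by an
  embedded LTASS-like breakpoint curve (flat 125–500 Hz, −6 dB/octave
  above 500 Hz, low cut below 125 Hz).
* **Fluctuating noise** — the same spectrum split at 800/2400 Hz into
  three bands, each multiplied by an independent syllabic on/off envelope
  (bursts 100–250 ms, pauses 50–200 ms, 20 ms ramps, unit-RMS normalized),
  so pauses never reach 250 ms and the modulation spectrum peaks at 2–8 Hz.
* **Word corpus** — each "word" is a fixed template of 2–3 tone glides
  (log-uniform 300–3500 Hz) plus a band-limited noise burst, 300–600 ms;
  tokens jitter duration ±5 % and pitch ±1 semitone.  Default demo size is
  10 words × 20 tokens at 65 dB SPL.

These are deliberate stand-ins: they emulate the *properties* that drive
the simulations (long-term speech spectrum; stationary vs. co-modulated
masking with bounded pauses; a small, separable, phonetically meaningless
vocabulary), not any real recording or language material.

## SRT simulation harness

One listening condition = masker kind × presentation level × listener
profile × processing.  Speech tokens are mixed with seeded random masker
fragments at each training SNR (default grid −30…+10 dB in 3 dB steps;
the scaled-down studies below use 6 dB steps), optionally processed, and
featurized.  The recognizer stand-in is a diagonal-Gaussian per-word
template classifier on time-pooled statistics: channel means over three
temporal segments plus channel standard deviations and delta standard
deviations (variances floored at 1e-3).  For each training SNR a template
set is estimated from disjoint training tokens and evaluated at every test
SNR, giving the recognition result map (% words correct).  The SRT for a
target rate is the lowest linear-interpolated crossing along the test axis,
minimized over training SNRs; censoring (target met at the grid edge, or
never) is flagged, not silently dropped.  Plomp curves tabulate SRT versus
masker level; the *benefit* of an aided arm is the mean of (unaided −
aided) SRT over 70/80/90 dB SPL, levels at which linear amplification
cannot change the outcome.  Psychometric segments evaluate targets
20…90 % in 5 % steps.

Conditions are simulated completely independently; nothing is shared or
calibrated across conditions.

## Problem sizes and runtime choices

The bundled direction-of-effect study uses 10 words × 20 tokens at
32 kHz (the lowest rate that carries the full channel grid), stationary
masker, training SNRs {−18, −12, −6, 0}, test SNRs −27…+15 in 6 dB steps,
masker levels 70/80/90 dB SPL.  Each SRT pools several hundred word
decisions.  Per-sample inner loops (filter cascade, envelope automaton,
slew limiter) are numba-compiled with a pure-numpy fallback.

## What the tests show — and what they cannot

Passing tests establish that the processing chain meets its printed design
constants and worked examples, that the class-D manipulations have the
level-independence that defines them, and that in this synthetic, scaled-
down world the compensation hypothesis behaves as expected: the simulated
SRT degrades monotonically with level uncertainty, expanding the 2–4 ERB
spectral-modulation band (factor 6) recovers a substantial part of the
deficit for high-uncertainty profiles, has no real effect for 1 dB
uncertainty, and identity processing has no effect anywhere.  None of this
quantifies benefits for real speech material, real maskers, or a full
GMM–HMM recognizer — absolute benefit values from the original study are
out of scope by construction, and the template classifier is far weaker
than a sequence recognizer, so only directions and orderings transfer.

Two figure-derived quantities disagree with this implementation's faithful
reading of the printed design text, and the corresponding checks are left
failing rather than reinterpreted: the envelope-peak delay near 800 Hz
measures ~3.7 ms against a figure-read "about 4.5 ms" (the −10 dB bandwidth
definition and the printed delays cannot both hold for a one-pole-cascade
Gammatone), and the two-tone d2 peak-to-peak span measures ~12–14 dB
against a "less than 9 dB" dynamic (the maximum *magnitude* of the d2
layer, ~8 dB, does satisfy the bound, as does the companion ~6 dB d1
claim).

## Known limitations

* Offline, whole-signal processing only; the real-time/blockwise and
  fixed-point engineering aspects are non-goals.
* No loudness model, no binaural processing, no frequency-dependent
  expansion factors.
* WAV I/O writes float32 or PCM16 only (reads PCM16/24/32/float).
* The harness's absolute percent-correct levels depend on the synthetic
  corpus geometry; only comparisons between arms are meaningful.
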