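# Methods

This note documents the models and conventions behind `maskedspeech`: what
each stage computes, the defaults and why, what the synthetic generators
emulate, and the limits of what passing tests demonstrate.

## Acoustic mask simulation

A face mask is modeled purely as a linear, time-invariant spectral loss.
Spectra are one-sided Welch averaged periodograms with a 512-point Hamming
window and 256-point overlap, expressed as `10·log10` of the power
estimate, at a working rate of 44.1 kHz (inputs at other rates should be
resampled on load; 44.1 kHz keeps the 16 kHz one-third-octave band below
Nyquist). The attenuation function is the reference-minus-masked dB
difference, clamped to ±30 dB before filter design so bins dominated by
measurement noise cannot produce absurd gains.

Two dB conventions are possible for "spectrum difference" (amplitude,
`20·log10`, vs power, `10·log10`); they coincide for broadband gains and
differ only by a fixed factor otherwise. This package fixes the power
convention for spectra and makes the filter design consistent with it: a
filter realizing attenuation `A` dB has amplitude response `10^(−A/20)`,
so re-estimating the Welch difference of filtered vs. original material
recovers `A`. All round-trip guarantees are stated in this convention.

Filters are type-I linear-phase FIRs from `scipy.signal.firwin2`
(frequency-sampling, the `fir2` family), order 128 → 129 symmetric taps.
"128-point" is read as the filter *order*; the 1-tap ambiguity is
immaterial at these transition bandwidths. The order must be even so a
type-I design with non-zero Nyquist gain exists. Applying a filter keeps
the input length and compensates the order/2 group delay, so span
annotations stay aligned (the last order/2 samples are zero-padded).
A zero-attenuation profile yields an exact unit impulse — the all-pass
control is flat to ~1e−13 dB.

Band summaries: the 2–16 kHz mean is an unweighted mean over the Welch
grid bins in the closed interval. One-third-octave bands use exact base-2
centers `1000·2^(n/3)` with edges `·2^(±1/6)` and are reported under their
conventional nominal labels (…, 3150, 4000, …, 16000 Hz); band means are
computed by linear interpolation on a 64-point log-spaced in-band grid
because the 86-Hz Welch spacing leaves the lowest standard bands with no
bins. Ties in the peak go to the lowest-frequency band.

The `synth_attenuation_profile` presets place a sigmoid high-frequency
shelf (knee 2 kHz, so |attenuation| < 1 dB below 1 kHz) plus a
Gaussian-in-log-frequency bump, scaled so the 2–16 kHz mean is exact by
construction: fabric-like 8.2 dB with the bump at 3.2 kHz, hospital-like
2.4 dB at 8 kHz, transparent-like 5.9 dB at 16 kHz — the measured ordering
of real masks (hospital mildest; fabric, here a dense two-layer cloth,
worst; transparents in between with their characteristic peak positions).

## Stimulus assembly

Levels are nominal: a `CalibrationMap` declares the dB SPL of a 0-dBFS-RMS
signal (default 100, putting the 70 dB SPL noise at −30 dBFS with ~4σ of
headroom over Gaussian noise peaks). No hardware calibration is implied.
SNR is defined on the RMS of the target's annotated speech span relative
to the noise RMS; the annotation is authoritative for both RMS
equalization and SNR, so silent padding never biases levels.

Trial timing defaults: 20-ms raised-cosine noise ramps (the ramp shape is
a package choice; only the duration is prescribed by the paradigm), video
186 ms after noise onset, ≥333 ms of neutral face before speech movement,
and speech onset at 776 ms (20-ms ramp + a 756-ms lead time typical of
edited CV recordings — a convention, not an enforced constraint). Per-trial noise is a seeded random contiguous excision from
the 30-s noise (the alternative, free-running looped noise, is not
modeled); the excision depends only on the trial seed, so SNR
manipulations reuse an identical noise floor. Samples outside the ramps
are exactly the scaled noise samples, and a mix that would clip raises an
error rather than limiting.

Speech-shaped noise is seeded white Gaussian noise through a 513-tap
linear-phase FIR following the square root of the reference power
spectrum, then rescaled by one scalar so its re-estimated spectrum sits on
the reference (mean dB offset over 0.1–10 kHz removed). Generation is
bit-exact for a fixed seed.

## Visual mask simulation

The canonical 66-point layout (17 jaw, 10 brow, 4 nose-bridge + 5
nostril, 12 eye, 18 lip points) is defined by this package; the original
tracker's index order is not public, so only the counts are inherited.
Opaque masks are one polygon through the jaw points closed via the top
nose-bridge point. The windowed mask reuses that outline with a hole equal
to the axis-aligned bounding box of the 18 lip points dilated by 0.2 ×
mouth width per side (configurable); the published mask shapes received
manual corrections that are not available, so this cutout is a defined
approximation, not a reproduction. Rendering uses hard-edged,
non-anti-aliased polygon fills (pure white), which makes it idempotent and
bit-exact testable. Occlusion accounting counts a landmark as covered if
it lies on or inside the mask (the jaw landmarks sit exactly on the
outline); points inside the cutout count as visible.

## Scoring

Confusion matrices pool counts over runs within a subject × condition
cell; incomplete blocks (not a multiple of 36 trials) can be excluded,
mirroring the treatment of abandoned runs. Feature transmission is
proportion-correct-by-feature — the share of trials whose response matches
the target's voicing / manner / place value — not Miller–Nicely
information transfer; it is bounded below by accuracy by construction.
Chance levels for a uniform responder are accuracy 1/12, voicing 1/2,
manner 54/144, place 50/144 (`Σ(n_c/12)²` over category sizes 6/6, 5/5/2,
4/5/3).

RAU uses the standard linear-rescaled two-term arcsine transform computed
from pooled counts per subject × condition (per-run transforms would be
noisier and are not the default). The continuous limit
`(146/π)·2·arcsin√p − 23` and its inverse are provided for simulation.

## Listener model

Each trial transmits the target's three features through independent
channels with probabilities `sigmoid(baseline_f + condition effect_f +
group offset + subject intercept)`; the response is uniform over
consonants consistent with every transmitted feature value. One deliberate
refinement: under the feature table /h/ and /sh/ share all three feature
values, so "all features transmitted" cannot identify the token by
features alone; the model therefore treats full three-channel transmission
as full token identification (response = target). This keeps the model
continuous in the channel probabilities and a perfect listener perfect,
and preserves the guarantee that measured transmission ≥ the configured
channel probability (chance matches only add).

Expected accuracy and transmissions are computed exactly by enumerating
the 2³ transmission patterns × uniform candidate draws per target; the
Monte-Carlo simulator is validated against this enumeration. Channel
independence is an explicit simplification, not a claim about human
perception: real confusions respect phonetic structure the model ignores,
so cohort-level simulations demonstrate pipeline correctness and power,
not human error patterns. The default condition preset reproduces the
qualitative ordering (auditory-only: hospital mildest, fabric worst;
audiovisual: mouth-visible conditions gain a boost concentrated on place;
visual-only: place transmitted best) for demonstrations only.

## Inference

Models are REML linear mixed-effects fits (statsmodels `MixedLM`) with a
random intercept per subject. Term-level F statistics are Wald tests on
each term's coefficient block. Denominator degrees of freedom use a
residual-style approximation, `n_obs − rank(X) − (n_subjects − 1)`;
lmerTest-style Satterthwaite df are not available in the fitting backend,
and at the designs used here (hundreds of residual df) the two agree
closely — the df are documented as approximate, and calibration is
verified by simulation rather than asserted. Backward elimination removes,
one at a time, the least-significant non-significant interaction among the
highest-order interactions not nested in a retained one (α = 0.05); main
effects are never removed, and the path is deterministic given the data.
Post hoc contrasts refit the retained model under new reference levels
(an equivalent reparameterization), with no multiplicity correction by
default, matching the source analysis convention; a correction can be
applied downstream. Between-group visual-only comparisons use Welch's
unequal-variance t-test with Welch–Satterthwaite df.

Simulation checks at experiment scale (20 subjects/group, 36 trials per cell,
true cell RAU → inverse-RAU proportion → binomial counts → RAU) show a
−10 RAU mask effect recovered with |bias| ≪ 1 RAU, ~95% Wald-CI coverage,
and term-level type-I error near 0.05 (200 effect replicates, 500 null
replicates — sizes chosen to estimate these rates within useful binomial
error). Coverage statements apply to the model matching the generative
form; estimates read off after data-driven elimination inherit the usual
post-selection caveats.

## Known limitations

- The acoustic model is LTI: no talker compensation (Lombard-style
  articulation changes), mask-fit variation, or room acoustics.
- The visual model renders geometry only: no mask texture, straps,
  fogging, or imperfect placement; landmark detection is consumed, not
  performed.
- Synthetic CV tokens are spectral caricatures (band-limited consonant
  noise + harmonic /i/); they carry the right annotations, durations, F0
  range, and cue-band structure for pipeline tests, but are not
  perceptually valid stimuli.
- The feature-channel listener cannot reproduce asymmetric human confusion
  patterns (e.g. voicing biases) and treats features as independent.
- Reported dB SPL values are nominal conversions through the calibration
  map, not acoustic measurements.
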