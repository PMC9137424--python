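# maskedspeech

Face masks degrade speech communication twice over: they attenuate the
high-frequency acoustic content that carries consonant cues, and they hide
the mouth movements listeners lip-read. `maskedspeech` is a Python package
for *simulating* both degradations and analyzing their perceptual
consequences with a closed-set consonant identification task — the paradigm
used to compare hospital, fabric, and transparent masks in children with
hearing loss (CHL), children with normal hearing (CNH), and adults with
normal hearing (ANH).

It is aimed at speech-perception and audiology researchers who want to
build mask-degraded audiovisual stimuli, pilot analysis pipelines, or run
power simulations without collecting human data first.

## What it does

**Acoustics.** The attenuation of a mask is measured as the difference of
long-term Welch magnitude spectra (512-point window, 256-point overlap)
between paired masked/unmasked recordings:
`A(f) = 10·log10 P_ref(f) − 10·log10 P_mask(f)`.
A 129-tap linear-phase FIR filter with magnitude response `10^(−A(f)/20)`
(frequency-sampling design, the `fir2` family) then imposes that loss on
clean studio recordings; a zero-attenuation input yields the all-pass
control applied to unmasked stimuli. Profiles are summarized as the mean
attenuation over 2–16 kHz and the peak mean within any standard
one-third-octave band (edges `center·2^(±1/6)`).

**Stimuli.** Speech-shaped noise is seeded Gaussian noise filtered to the
long-term spectrum of the target speech. Trials place an RMS-equalized CV
token (12 consonants × /i/) into noise gated with 20-ms raised-cosine
ramps; a calibration map (0 dBFS RMS ↔ 100 dB SPL by default) converts the
nominal 70 dB SPL noise level and the requested SNR into exact digital
gains, with SNR defined on the speech-span RMS.

**Visual.** Masks are filled white polygons anchored to 66 facial
landmarks: opaque masks use the 17 jaw-line points closed through the top
nose-bridge point; the windowed (Communicator-style) mask adds a
transparent cutout over the lips; a fully transparent mask draws nothing.

**Scoring.** Responses are tabulated into 12×12 confusion matrices;
accuracy and the transmission of voicing, manner, and place of
articulation (the proportion of responses sharing the target's feature
value) are computed per subject × condition and mapped to rationalized
arcsine units, `RAU = (146/π)·[arcsin√(X/(N+1)) + arcsin√((X+1)/(N+1))] − 23`,
for linear modeling. Audiovisual benefit is the AV − AO RAU difference.

**Inference.** RAU scores are fitted with linear mixed-effects models
(REML, random intercept per subject; fixed factorial of mask × modality ×
group), with backward elimination of non-significant interactions,
re-leveled post hoc contrasts, and Welch's *t*-tests for between-group
comparisons outside the factorial design.

**Synthetic data.** Every input can be generated: CV-like tokens (728–941
ms, F0 ≈ 238 Hz, consonant-specific high-frequency cue bands), mask-like
attenuation profiles, masked/unmasked recording pairs with known ground
truth, landmark sequences with controllable mouth aperture, and listener
cohorts driven by a feature-channel confusion model with factorial
condition effects and subject random intercepts on the logit scale.

## Worked example

```python
import numpy as np
from maskedspeech import synthetic as syn, scoring as sc, inference as inf
from maskedspeech.acoustics import (estimate_magnitude_spectrum,
                                    attenuation_function, summarize_attenuation)

# recover a mask profile from a synthetic masked/unmasked recording pair
profile = syn.synth_attenuation_profile("fabric-like")
ref, masked = syn.synth_masked_pair(profile, duration_s=60.0, seed=1)
recovered = attenuation_function(estimate_magnitude_spectrum(masked),
                                 estimate_magnitude_spectrum(ref))
s = summarize_attenuation(recovered)
print(f"mean 2-16 kHz attenuation: {s.mean_2_16k_db:.1f} dB")
print(f"peak 1/3-octave: {s.peak_third_octave_db:.1f} dB at {s.peak_center_hz:.0f} Hz")

# simulate a small cohort, score it, and fit the accuracy model
design = syn.CohortDesign(n_per_group={"CHL": 6, "CNH": 6, "ANH": 6})
trials = syn.simulate_cohort(design, syn.default_listener_params(), seed=1)
scores = sc.score_table(trials)
av = scores[scores["modality"].isin(["AO", "AV"])].reset_index(drop=True)
model = inf.fit_accuracy_model(av, inf.ModelSpec())
fab = model.coefficients.set_index("term").loc[
    "C(mask, Treatment('none'))[T.fabric]"]
print(f"fabric-mask effect (AO, re: no mask): {fab['estimate']:.1f} RAU "
      f"(SE {fab['se']:.1f})")
```

prints

```
mean 2-16 kHz attenuation: 8.2 dB
peak 1/3-octave: 10.6 dB at 3150 Hz
fabric-mask effect (AO, re: no mask): -20.8 RAU (SE 1.9)
```

The recovered profile reproduces the generator's 8.2-dB fabric-mask band
mean with its one-third-octave peak in the 3150-Hz band. In the simulated
cohort the fabric mask costs about 21 RAU auditory-only relative to no
mask (the default listener preset orders masks the way the acoustics
predict: hospital mildest, fabric worst); the retained mask × modality
interaction reflects the visual boost transparent masks preserve in
audiovisual conditions.

A command-line interface mirrors the library
(`maskedspeech derive-filter | apply-mask | summarize-attenuation |
make-noise | mix | occlude | simulate-cohort | score | analyze | run`).

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
conventions, and what the synthetic generators do and do not emulate.
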