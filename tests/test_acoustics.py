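"""Spectrum estimation, attenuation functions, and FIR mask filters."""

import numpy as np
import pytest

from maskedspeech.acoustics import (
    AttenuationFunction,
    Waveform,
    apply_filter,
    attenuation_function,
    band_mean_attenuation,
    design_mask_filter,
    estimate_magnitude_spectrum,
    peak_third_octave_attenuation,
    third_octave_bands,
)

RATE = 44100


def default_grid():
    return np.linspace(0.0, RATE / 2.0, 257)


class TestSpectrumEstimate:
    def test_default_grid_has_257_bins_to_nyquist(self, white_noise_60s):
        spec = estimate_magnitude_spectrum(white_noise_60s)
        assert len(spec.frequencies) == 257
        assert spec.frequencies[0] == 0.0
        assert spec.frequencies[-1] == pytest.approx(22050.0)

    def test_sinusoid_peaks_at_its_own_bin(self):
        f_bin = 86.1328125 * 50  # 50th bin of the 512-point grid
        t = np.arange(RATE * 2) / RATE
        spec = estimate_magnitude_spectrum(Waveform(np.sin(2 * np.pi * f_bin * t), RATE))
        assert spec.frequencies[np.argmax(spec.magnitude_db)] == pytest.approx(f_bin)

    def test_long_white_noise_is_flat(self, white_noise_spectrum):
        spec = white_noise_spectrum
        band = (spec.frequencies >= 100) & (spec.frequencies <= 20000)
        mags = spec.magnitude_db[band]
        assert np.max(np.abs(mags - mags.mean())) < 1.0

    def test_too_short_signal_raises(self):
        with pytest.raises(ValueError, match="too short"):
            estimate_magnitude_spectrum(Waveform(np.zeros(1000), RATE))


class TestAttenuationFunction:
    def test_identical_spectra_give_zero(self, white_noise_spectrum):
        att = attenuation_function(white_noise_spectrum, white_noise_spectrum)
        assert np.allclose(att.attenuation_db, 0.0)

    def test_broadband_gain_is_recovered(self, white_noise_60s):
        scaled = Waveform(white_noise_60s.samples * 10 ** (-6 / 20), RATE)
        att = attenuation_function(
            estimate_magnitude_spectrum(scaled),
            estimate_magnitude_spectrum(white_noise_60s),
        )
        assert np.allclose(att.attenuation_db, 6.0, atol=0.1)

    def test_grid_mismatch_names_both_grids(self, white_noise_60s):
        a = estimate_magnitude_spectrum(white_noise_60s)
        b = estimate_magnitude_spectrum(white_noise_60s, nperseg=1024, noverlap=512)
        with pytest.raises(ValueError, match="frequency grids differ"):
            attenuation_function(a, b)

    def test_clamped_to_configured_bounds(self, white_noise_spectrum):
        spec = white_noise_spectrum
        quiet = type(spec)(spec.frequencies, spec.magnitude_db - 80.0, spec.rate)
        att = attenuation_function(quiet, spec, clamp_db=30.0)
        assert att.attenuation_db.max() == pytest.approx(30.0)


class TestMaskFilter:
    def test_allpass_is_flat_within_tenth_db(self):
        att = AttenuationFunction(default_grid(), np.zeros(257))
        filt = design_mask_filter(att, order=128)
        freqs = np.geomspace(50, 20000, 400)
        assert np.max(np.abs(filt.magnitude_db(freqs))) < 0.1

    def test_taps_count_and_symmetry(self, fabric_profile):
        filt = design_mask_filter(fabric_profile, order=128)
        assert len(filt.taps) == 129
        assert np.allclose(filt.taps, filt.taps[::-1], atol=1e-9)

    def test_shelf_design_tracks_target_outside_transition(self):
        freqs = default_grid()
        shelf = 10.0 / (1.0 + (np.maximum(freqs, 1.0) / 4000.0) ** -8)
        att = AttenuationFunction(freqs, shelf)
        filt = design_mask_filter(att, order=128)
        # exclude one-third octave around the 4 kHz knee
        eval_f = np.geomspace(100, 20000, 300)
        keep = (eval_f < 4000 * 2 ** (-1 / 6)) | (eval_f > 4000 * 2 ** (1 / 6))
        target_db = -np.interp(eval_f, freqs, shelf)
        err = filt.magnitude_db(eval_f[keep]) - target_db[keep]
        assert np.max(np.abs(err)) < 1.0

    @pytest.mark.parametrize("order", [7, 9])
    def test_bad_order_rejected(self, order):
        att = AttenuationFunction(default_grid(), np.zeros(257))
        with pytest.raises(ValueError):
            design_mask_filter(att, order=order)


class TestApplyFilter:
    def test_allpass_is_delay_compensated_identity(self):
        rng = np.random.default_rng(0)
        wave = Waveform(rng.standard_normal(RATE) * 0.1, RATE)
        att = AttenuationFunction(default_grid(), np.zeros(257))
        out = apply_filter(wave, design_mask_filter(att))
        # tail is zero-padded, so compare away from the edge
        n = len(wave) - 200
        resid = out.samples[:n] - wave.samples[:n]
        assert np.sqrt(np.mean(resid**2)) < 1e-6

    def test_sinusoid_attenuated_by_design_value(self, fabric_profile):
        filt = design_mask_filter(fabric_profile)
        t = np.arange(RATE) / RATE
        wave = Waveform(0.3 * np.sin(2 * np.pi * 8000 * t), RATE)
        out = apply_filter(wave, filt)
        drop = 20 * np.log10(
            np.sqrt(np.mean(wave.samples[2000:-2000] ** 2))
            / np.sqrt(np.mean(out.samples[2000:-2000] ** 2))
        )
        assert drop == pytest.approx(fabric_profile.at(8000.0), abs=0.5)

    def test_rate_mismatch_rejected(self, fabric_profile):
        filt = design_mask_filter(fabric_profile)
        with pytest.raises(ValueError, match="rate"):
            apply_filter(Waveform(np.zeros(1000), 16000), filt)

    def test_fabric_filter_hits_consonant_harder_than_vowel(self, fabric_profile):
        from maskedspeech.synthetic import synth_cv_token

        tok = synth_cv_token("s", seed=0)
        out = apply_filter(tok, design_mask_filter(fabric_profile))
        a, b = tok.annotations["consonant"]
        cons_drop = np.std(tok.samples[a:b]) / np.std(out.samples[a:b])
        vowel_drop = np.std(tok.samples[b:]) / np.std(out.samples[b:])
        assert cons_drop > vowel_drop


class TestBandSummaries:
    def test_constant_profile_mean_equals_constant(self):
        att = AttenuationFunction(default_grid(), np.full(257, 6.0))
        assert band_mean_attenuation(att, 2000, 16000) == pytest.approx(6.0)
        assert band_mean_attenuation(att, 100, 500) == pytest.approx(6.0)

    def test_mean_invariant_to_common_offset(self, white_noise_60s):
        ref = estimate_magnitude_spectrum(white_noise_60s)
        masked = type(ref)(ref.frequencies, ref.magnitude_db - 4.0, ref.rate)
        att1 = attenuation_function(masked, ref)
        shifted_ref = type(ref)(ref.frequencies, ref.magnitude_db + 11.0, ref.rate)
        shifted_masked = type(ref)(ref.frequencies, masked.magnitude_db + 11.0, ref.rate)
        att2 = attenuation_function(shifted_masked, shifted_ref)
        assert band_mean_attenuation(att1, 2000, 16000) == pytest.approx(
            band_mean_attenuation(att2, 2000, 16000)
        )

    def test_empty_band_raises(self, fabric_profile):
        with pytest.raises(ValueError):
            band_mean_attenuation(fabric_profile, 22000, 22040)

    def test_constant_profile_peak_ties_to_lowest_band(self):
        att = AttenuationFunction(default_grid(), np.full(257, 5.0))
        peak_db, center = peak_third_octave_attenuation(att)
        assert peak_db == pytest.approx(5.0, abs=1e-9)
        assert center == 100.0

    def test_notch_spanning_one_band_is_found(self):
        freqs = default_grid()
        lo, hi = 3150 / 1.0, 3150.0  # placeholder, replaced below
        exact = 1000 * 2 ** (5 / 3)
        lo, hi = exact * 2 ** (-1 / 6), exact * 2 ** (1 / 6)
        att_db = np.where((freqs >= lo) & (freqs <= hi), 15.0, 0.0)
        att = AttenuationFunction(freqs, att_db)
        peak_db, center = peak_third_octave_attenuation(att)
        assert center == 3150.0
        assert peak_db == pytest.approx(15.0, abs=1.0)

    def test_band_edges_are_sixth_octave(self):
        bands = third_octave_bands(22050.0)
        assert bands[-1][0] == 16000.0
        for _, lo, hi in bands:
            assert hi / lo == pytest.approx(2 ** (1 / 3))


def test_roundtrip_design_apply_estimate(fabric_profile, white_noise_60s):
    """Design -> filter -> re-estimate recovers a smooth profile within 1 dB."""
    filt = design_mask_filter(fabric_profile)
    filtered = apply_filter(white_noise_60s, filt)
    att = attenuation_function(
        estimate_magnitude_spectrum(filtered),
        estimate_magnitude_spectrum(white_noise_60s),
    )
    sel = (att.frequencies >= 200) & (att.frequencies <= 10000)
    err = att.attenuation_db[sel] - fabric_profile.attenuation_db[sel]
    assert np.max(np.abs(err)) < 1.0
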