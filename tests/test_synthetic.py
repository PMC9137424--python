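"""Generators: tokens, profiles, recording pairs, landmarks, listeners."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from maskedspeech.acoustics import (
    attenuation_function,
    band_mean_attenuation,
    estimate_magnitude_spectrum,
)
from maskedspeech.scoring import CONSONANTS, DEFAULT_SCHEME
from maskedspeech.synthetic import (
    STUDY_CONDITIONS,
    CohortDesign,
    ListenerParams,
    default_listener_params,
    expected_feature_transmission,
    simulate_cohort,
    simulate_listener,
    synth_attenuation_profile,
    synth_cv_token,
    synth_face_landmarks,
    synth_masked_pair,
)


class TestCvTokens:
    @pytest.mark.parametrize("consonant", ["b", "s", "m", "sh"])
    def test_duration_within_study_range(self, consonant):
        tok = synth_cv_token(consonant, seed=11)
        assert 0.728 <= tok.duration_s <= 0.941

    def test_same_seed_identical_different_seed_not(self):
        a = synth_cv_token("t", seed=5)
        b = synth_cv_token("t", seed=5)
        c = synth_cv_token("t", seed=6)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_s_consonant_energy_concentrates_above_3k(self):
        tok = synth_cv_token("s", seed=2)
        a, b = tok.annotations["consonant"]
        seg = tok.samples[a:b]
        freqs = np.fft.rfftfreq(len(seg), 1 / tok.rate)
        power = np.abs(np.fft.rfft(seg)) ** 2
        frac_high = power[freqs > 3000].sum() / power.sum()
        assert frac_high > 0.7

    def test_annotations_cover_token(self):
        tok = synth_cv_token("z", seed=1)
        assert tok.annotations["speech"] == (0, len(tok))
        ca, cb = tok.annotations["consonant"]
        assert ca == 0 and 0 < cb < len(tok)


class TestAttenuationProfiles:
    def test_none_kind_is_zero(self):
        prof = synth_attenuation_profile("none")
        assert np.allclose(prof.attenuation_db, 0.0)

    def test_fabric_mean_matches_construction(self, fabric_profile):
        assert band_mean_attenuation(fabric_profile, 2000, 16000) == pytest.approx(
            8.2, abs=0.2)

    @pytest.mark.parametrize("kind", ["hospital-like", "fabric-like",
                                      "transparent-like"])
    def test_below_1khz_is_nearly_transparent(self, kind):
        prof = synth_attenuation_profile(kind)
        low = prof.attenuation_db[prof.frequencies < 1000]
        assert np.max(np.abs(low)) < 1.0

    def test_parametric_kind_honors_requested_mean(self):
        prof = synth_attenuation_profile("parametric", mean_2_16k_db=4.0,
                                         bump_center_hz=5000.0)
        assert band_mean_attenuation(prof, 2000, 16000) == pytest.approx(4.0)


class TestMaskedPair:
    def test_zero_profile_no_noise_pair_identical(self):
        prof = synth_attenuation_profile("none")
        ref, masked = synth_masked_pair(prof, duration_s=2.0, seed=0,
                                        measurement_noise_db=-np.inf)
        n = len(ref) - 200  # zero-padded filter tail
        assert np.allclose(ref.samples[:n], masked.samples[:n], atol=1e-6)

    def test_seeded_pair_reproducible(self, fabric_profile):
        a = synth_masked_pair(fabric_profile, duration_s=2.0, seed=3)
        b = synth_masked_pair(fabric_profile, duration_s=2.0, seed=3)
        assert np.array_equal(a[0].samples, b[0].samples)
        assert np.array_equal(a[1].samples, b[1].samples)

    def test_profile_recovered_within_1_db(self, fabric_profile):
        ref, masked = synth_masked_pair(fabric_profile, duration_s=30.0, seed=1)
        rec = attenuation_function(
            estimate_magnitude_spectrum(masked),
            estimate_magnitude_spectrum(ref),
        )
        sel = (rec.frequencies >= 200) & (rec.frequencies <= 10000)
        err = rec.attenuation_db[sel] - fabric_profile.attenuation_db[sel]
        assert np.max(np.abs(err)) < 1.0


class TestFaceLandmarks:
    def test_single_frame_is_valid(self):
        frames = synth_face_landmarks(1, seed=0)
        assert len(frames) == 1  # LandmarkFrame validates itself on build

    def test_zero_aperture_inner_lips_coincide(self):
        frames = synth_face_landmarks(3, aperture_px=0.0, jitter_px=0.0, seed=0)
        for frame in frames:
            upper = frame.points[60:63]
            lower = frame.points[63:66]
            assert np.max(np.abs(upper - lower)) < 1.0

    def test_seeded_sequence_reproducible(self):
        a = synth_face_landmarks(4, seed=9)
        b = synth_face_landmarks(4, seed=9)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.points, fb.points)


class TestListenerModel:
    def test_perfect_channels_always_correct(self):
        rng = np.random.default_rng(0)
        probs = {"voicing": 1.0, "manner": 1.0, "place": 1.0}
        for target in CONSONANTS:
            assert simulate_listener(target, probs, rng) == target

    def test_dead_channels_respond_uniformly(self):
        rng = np.random.default_rng(1)
        probs = {"voicing": 0.0, "manner": 0.0, "place": 0.0}
        responses = [simulate_listener("k", probs, rng) for _ in range(12000)]
        counts = pd.Series(responses).value_counts().reindex(CONSONANTS).fillna(0)
        chi2, p = stats.chisquare(counts)
        assert p > 0.001

    def test_enumeration_reduces_to_chance_and_certainty(self):
        certain = expected_feature_transmission(
            {"voicing": 1.0, "manner": 1.0, "place": 1.0})
        assert certain["accuracy"] == pytest.approx(1.0)
        dead = expected_feature_transmission(
            {"voicing": 0.0, "manner": 0.0, "place": 0.0})
        assert dead["accuracy"] == pytest.approx(1 / 12)
        assert dead["voicing"] == pytest.approx(0.5)
        assert dead["place"] == pytest.approx(50 / 144)

    def test_empirical_transmission_matches_enumeration(self):
        probs = {"voicing": 0.9, "manner": 0.9, "place": 0.9}
        expected = expected_feature_transmission(probs)
        rng = np.random.default_rng(7)
        n = 10000
        hits = {f: 0 for f in ("voicing", "manner", "place")}
        for i in range(n):
            target = CONSONANTS[i % 12]
            resp = simulate_listener(target, probs, rng)
            for f in hits:
                hits[f] += (DEFAULT_SCHEME.features[f][resp]
                            == DEFAULT_SCHEME.features[f][target])
        for f, count in hits.items():
            p_hat = count / n
            se = np.sqrt(expected[f] * (1 - expected[f]) / n)
            assert abs(p_hat - expected[f]) < 3 * se

    def test_transmission_at_least_channel_probability(self):
        # chance matches only add on top of the transmitted-channel rate
        for p in (0.3, 0.6, 0.9):
            probs = {"voicing": p, "manner": p, "place": p}
            expected = expected_feature_transmission(probs)
            for f in ("voicing", "manner", "place"):
                assert expected[f] >= p


@pytest.fixture(scope="module")
def small_trials():
    design = CohortDesign(n_per_group={"CHL": 2, "CNH": 2, "ANH": 2},
                          runs_per_condition=1)
    return simulate_cohort(design, default_listener_params(), seed=3)


class TestCohort:
    def test_block_structure_36_trials_per_cell(self, small_trials):
        sizes = small_trials.groupby(["subject_id", "mask", "modality"]).size()
        assert (sizes == 36).all()
        targets = small_trials.groupby(
            ["subject_id", "mask", "modality", "target"]).size()
        assert (targets == 3).all()

    def test_all_11_conditions_present(self, small_trials):
        cells = set(map(tuple, small_trials[["mask", "modality"]]
                        .drop_duplicates().itertuples(index=False)))
        assert cells == set(STUDY_CONDITIONS)

    def test_extreme_listener_is_always_correct(self):
        params = ListenerParams(
            baseline_logit={"voicing": 30.0, "manner": 30.0, "place": 30.0},
            subject_sd=0.0)
        design = CohortDesign(n_per_group={"CNH": 1}, runs_per_condition=1,
                              conditions=(("none", "AO"),))
        trials = simulate_cohort(design, params, seed=0)
        assert (trials["target"] == trials["response"]).all()

    def test_seeded_cohort_reproducible(self):
        design = CohortDesign(n_per_group={"CNH": 1}, runs_per_condition=1,
                              conditions=(("none", "AO"), ("fabric", "AO")))
        a = simulate_cohort(design, seed=5)
        b = simulate_cohort(design, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError, match="conditions"):
            CohortDesign(conditions=(("fabric", "VO"),))
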