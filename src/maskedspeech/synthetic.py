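"""Synthetic inputs for every pipeline stage.

Nothing in this package requires the original recordings: this module
generates CV-like speech tokens, mask attenuation profiles shaped like the
measured ones, masked/unmasked recording pairs with known ground truth,
66-point facial landmark sequences, and simulated listener cohorts whose
feature transmission is controllable.

The listener is a feature-channel model: on each trial the three
articulatory features of the target (voicing, manner, place) are each
"transmitted" independently with a condition-specific probability, and the
response is drawn uniformly from the consonants consistent with every
transmitted feature value.  This is an explicit simplification — human
confusions are not feature-independent — chosen because it makes expected
transmission computable exactly by enumeration and guarantees measured
transmission is at least the configured channel probability.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .acoustics import (
    DEFAULT_RATE,
    AttenuationFunction,
    Waveform,
    apply_filter,
    band_mean_attenuation,
    design_mask_filter,
)
from .scoring import CONSONANTS, DEFAULT_SCHEME, FeatureScheme, rau
from .visual import N_LANDMARKS, LandmarkFrame

__all__ = [
    "ListenerParams",
    "CohortDesign",
    "STUDY_CONDITIONS",
    "synth_cv_token",
    "synth_attenuation_profile",
    "synth_masked_pair",
    "synth_face_landmarks",
    "simulate_listener",
    "expected_feature_transmission",
    "simulate_cohort",
    "simulate_rau_scores",
    "default_listener_params",
]

# ---------------------------------------------------------------------------
# CV-like tokens

#: Noise band (Hz) of the consonant segment and its duration (s) per
#: consonant.  Fricatives get long high bands, stops short bursts, nasals a
#: low murmur band.  Values are caricatures sufficient to give each
#: consonant a distinct spectral cue region.
_CONSONANT_BANDS: dict[str, tuple[float, float, float]] = {
    "b": (300, 900, 0.06),
    "d": (2500, 5000, 0.06),
    "k": (1500, 3500, 0.06),
    "p": (500, 1500, 0.06),
    "t": (3000, 6000, 0.06),
    "s": (4500, 9000, 0.18),
    "sh": (2200, 5500, 0.18),
    "z": (3800, 8000, 0.16),
    "v": (600, 1800, 0.14),
    "h": (1000, 3000, 0.12),
    "m": (200, 500, 0.12),
    "n": (250, 600, 0.12),
}

#: Token duration range (s) and F0 statistics (Hz) the generator targets.
TOKEN_DURATION_S = (0.728, 0.941)
TOKEN_F0_HZ = (238.0, 10.0)  # mean, SD


def _token_rng(consonant: str, seed: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), CONSONANTS.index(consonant)])
    )


def synth_cv_token(consonant: str, seed: int = 0,
                   rate: int = DEFAULT_RATE) -> Waveform:
    """A CV-like token: consonant-band noise followed by a harmonic /i/ vowel.

    Total duration is drawn uniformly from 728-941 ms and F0 from
    N(238, 10) Hz.  The vowel is a harmonic complex with /i/-like formant
    resonances (270 and 2300 Hz); the consonant segment is band-limited
    noise in a consonant-specific region.  Annotations: ``speech`` spans the
    whole token, ``consonant`` the initial segment.
    """
    if consonant not in CONSONANTS:
        raise ValueError(f"unknown consonant {consonant!r}")
    rng = _token_rng(consonant, seed)
    f_lo, f_hi, cons_dur = _CONSONANT_BANDS[consonant]
    total_dur = rng.uniform(*TOKEN_DURATION_S)
    f0 = float(np.clip(rng.normal(*TOKEN_F0_HZ), 212.0, 276.0))

    n_cons = int(round(cons_dur * rate))
    n_vowel = int(round(total_dur * rate)) - n_cons

    sos = _sig.butter(4, [f_lo, f_hi], btype="bandpass", fs=rate, output="sos")
    cons = _sig.sosfilt(sos, rng.standard_normal(n_cons))
    cons *= _sig.windows.tukey(n_cons, 0.4)
    cons *= 0.35 / max(np.sqrt(np.mean(cons**2)), 1e-12)

    t = np.arange(n_vowel) / rate
    vowel = np.zeros(n_vowel)
    for k in range(1, int(10000 // f0) + 1):
        fk = k * f0
        # /i/-like spectral envelope: two resonances + high-frequency rolloff
        amp = (
            np.exp(-0.5 * (np.log2(fk / 270.0) / 0.6) ** 2)
            + 0.4 * np.exp(-0.5 * (np.log2(fk / 2300.0) / 0.4) ** 2)
        ) / (1.0 + fk / 3000.0)
        vowel += amp * np.sin(2 * np.pi * fk * t + rng.uniform(0, 2 * np.pi))
    vowel *= _sig.windows.tukey(n_vowel, 0.15)
    vowel *= 0.5 / max(np.sqrt(np.mean(vowel**2)), 1e-12)

    samples = np.concatenate([cons, vowel])
    samples *= 0.1 / max(np.sqrt(np.mean(samples**2)), 1e-12)
    n = len(samples)
    return Waveform(samples, rate,
                    {"speech": (0, n), "consonant": (0, n_cons)})


# ---------------------------------------------------------------------------
# Attenuation profiles

#: Preset (mean 2-16 kHz attenuation dB, bump center Hz) per profile kind,
#: matching the measured per-mask band summaries.
PROFILE_PRESETS: dict[str, tuple[float, float]] = {
    "hospital-like": (2.4, 8000.0),
    "fabric-like": (8.2, 3200.0),
    "transparent-like": (5.9, 16000.0),
}


def synth_attenuation_profile(
    kind: str = "fabric-like",
    mean_2_16k_db: float | None = None,
    bump_center_hz: float | None = None,
    bump_width_oct: float = 0.5,
    bump_rel: float = 0.5,
    shelf_knee_hz: float = 2000.0,
    rate: int = DEFAULT_RATE,
    n_bins: int = 257,
) -> AttenuationFunction:
    """Smooth mask-like attenuation profile on the standard spectral grid.

    The shape is a high-frequency shelf (sigmoid in log frequency with knee
    at 2 kHz, so attenuation is ~0 below 1 kHz) plus a Gaussian-in-log-f
    bump, scaled so the 2-16 kHz band mean equals ``mean_2_16k_db``
    exactly by construction.  Presets: ``none``, ``hospital-like``,
    ``fabric-like`` and ``transparent-like``, whose means and bump centers
    follow the measured per-mask summaries.
    """
    freqs = np.linspace(0.0, rate / 2.0, n_bins)
    if kind == "none":
        return AttenuationFunction(freqs, np.zeros(n_bins), provenance="none")
    if kind == "parametric":
        if mean_2_16k_db is None or bump_center_hz is None:
            raise ValueError("parametric profile needs mean_2_16k_db and bump_center_hz")
    elif kind in PROFILE_PRESETS:
        preset_mean, preset_center = PROFILE_PRESETS[kind]
        mean_2_16k_db = preset_mean if mean_2_16k_db is None else mean_2_16k_db
        bump_center_hz = preset_center if bump_center_hz is None else bump_center_hz
    else:
        raise ValueError(f"unknown profile kind {kind!r}")

    with np.errstate(divide="ignore"):
        logf = np.log2(np.maximum(freqs, 1.0) / shelf_knee_hz)
    shelf = 0.5 * (1.0 + np.tanh(logf / 0.5))
    bump = bump_rel * np.exp(
        -0.5 * (np.log2(np.maximum(freqs, 1.0) / bump_center_hz) / bump_width_oct) ** 2
    )
    shape = shelf + bump
    shape[freqs < 1.0] = 0.0
    att = AttenuationFunction(freqs, shape, provenance=kind)
    scale = mean_2_16k_db / band_mean_attenuation(att, 2000.0, 16000.0)
    return AttenuationFunction(freqs, shape * scale, provenance=kind)


def synth_masked_pair(
    profile: AttenuationFunction,
    duration_s: float = 60.0,
    seed: int = 0,
    measurement_noise_db: float = -70.0,
    rate: int = DEFAULT_RATE,
) -> tuple[Waveform, Waveform]:
    """Paired recordings with a known ground-truth attenuation profile.

    The reference is a speech-shaped (low-pass tilted) noise; the masked
    member is the same signal through a FIR filter realizing ``profile``,
    plus small independent measurement noise on both channels
    (``measurement_noise_db`` relative to the reference RMS; 0 dB of noise
    is disabled with ``-np.inf``).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    n = int(round(duration_s * rate))
    white = rng.standard_normal(n)
    # -6 dB/oct tilt above 500 Hz approximates a long-term speech spectrum
    b, a = _sig.butter(1, 500.0, btype="lowpass", fs=rate)
    speechish = _sig.lfilter(b, a, white) + 0.05 * white
    speechish /= np.sqrt(np.mean(speechish**2))

    reference = Waveform(speechish, rate)
    filt = design_mask_filter(profile, order=128)
    masked = apply_filter(reference, filt)

    if np.isfinite(measurement_noise_db):
        eps = 10.0 ** (measurement_noise_db / 20.0)
        ref_s = reference.samples + eps * rng.standard_normal(n)
        msk_s = masked.samples + eps * rng.standard_normal(n)
        reference, masked = Waveform(ref_s, rate), Waveform(msk_s, rate)
    return reference, masked


# ---------------------------------------------------------------------------
# Facial landmarks

def _face_template(aperture: float, jaw_drop: float) -> np.ndarray:
    """Canonical 66-point face for a 640x480 frame.

    ``aperture`` is the inner-lip opening in pixels (0 = closed);
    ``jaw_drop`` lowers the chin and lips as the mouth opens.
    """
    pts = np.zeros((N_LANDMARKS, 2))
    # jaw 0-16: lower-face ellipse arc, left temple -> chin -> right temple
    phi = np.pi * (1.0 + np.arange(17) / 16.0)
    pts[0:17, 0] = 320 + 120 * np.cos(phi)
    pts[0:17, 1] = 220 - 160 * np.sin(phi) + jaw_drop * np.maximum(0, -np.sin(phi))
    # brows 17-26
    for side, x0 in ((0, 245), (1, 345)):
        xs = x0 + 12.5 * np.arange(5)
        pts[17 + 5 * side:22 + 5 * side, 0] = xs
        pts[17 + 5 * side:22 + 5 * side, 1] = 150 - 4 * np.sin(
            np.linspace(0, np.pi, 5))
    # nose bridge 27-30 (27 = top middle) and nostril base 31-35
    pts[27:31] = [(320, 190), (320, 210), (320, 230), (320, 248)]
    pts[31:36, 0] = [300, 310, 320, 330, 340]
    pts[31:36, 1] = 262
    # eyes 36-47: two hexagons
    ang = np.deg2rad(np.arange(0, 360, 60))
    for side, cx in ((0, 270), (1, 370)):
        pts[36 + 6 * side:42 + 6 * side, 0] = cx + 18 * np.cos(ang)
        pts[36 + 6 * side:42 + 6 * side, 1] = 180 - 7 * np.sin(ang)
    # lips 48-65: 12-point outer rim + 6-point inner rim
    cy = 315 + jaw_drop / 2.0
    theta = np.deg2rad(np.arange(0, 360, 30))
    ry = np.where(np.sin(theta) >= 0, 10.0, 14.0 + aperture)
    pts[48:60, 0] = 320 + 45 * np.cos(theta)
    pts[48:60, 1] = cy - ry * np.sin(theta)
    xs = np.array([300.0, 320.0, 340.0])
    pts[60:63, 0] = xs
    pts[60:63, 1] = cy - aperture / 2.0
    pts[63:66, 0] = xs
    pts[63:66, 1] = cy + aperture / 2.0
    return pts


def synth_face_landmarks(
    n_frames: int,
    aperture_px: float = 10.0,
    cycle_frames: int = 20,
    jitter_px: float = 0.2,
    seed: int = 0,
    frame_size: tuple[int, int] = (640, 480),
) -> list[LandmarkFrame]:
    """Smooth talking-face landmark sequence with controllable mouth opening.

    The mouth opens and closes sinusoidally with period ``cycle_frames``
    and maximum inner-lip aperture ``aperture_px`` (0 keeps the inner-lip
    points coincident); the jaw follows.  Small seeded Gaussian jitter
    emulates tracker noise without violating any layout invariant.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        opening = 0.5 * (1 - np.cos(2 * np.pi * i / cycle_frames))
        aperture = aperture_px * opening
        pts = _face_template(aperture, jaw_drop=0.8 * aperture)
        pts = pts + rng.normal(0.0, jitter_px, pts.shape)
        frames.append(LandmarkFrame(i, pts, frame_size=frame_size))
    return frames


# ---------------------------------------------------------------------------
# Listener model

def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


FEATURES = ("voicing", "manner", "place")

#: The protocol's 11 conditions: 5 masks x {AO, AV} minus masked VO, plus
#: unmasked VO.
STUDY_CONDITIONS: tuple[tuple[str, str], ...] = tuple(
    [(m, mod) for mod in ("AO", "AV")
     for m in ("none", "hospital", "fabric", "communicator", "clearmask")]
    + [("none", "VO")]
)


@dataclass(frozen=True)
class ListenerParams:
    """Feature-channel listener with factorial condition structure.

    Transmission probability of feature ``f`` for subject ``i`` in
    condition ``(mask, modality)`` is
    ``sigmoid(baseline[f] + condition_effects[(mask, modality)][f]
    + group_offsets[group] + b_i)`` with ``b_i ~ N(0, subject_sd)`` on the
    logit scale, shared across features within subject.
    """

    baseline_logit: dict = field(
        default_factory=lambda: {"voicing": 1.4, "manner": 0.8, "place": 0.2}
    )
    condition_effects: dict = field(default_factory=dict)
    group_offsets: dict = field(
        default_factory=lambda: {"CHL": -0.8, "CNH": 0.0, "ANH": 0.2}
    )
    subject_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")

    def probabilities(self, mask: str, modality: str, group: str = "CNH",
                      subject_effect: float = 0.0) -> dict[str, float]:
        eff = self.condition_effects.get((mask, modality), {})
        return {
            f: _sigmoid(
                self.baseline_logit[f]
                + eff.get(f, 0.0)
                + self.group_offsets.get(group, 0.0)
                + subject_effect
            )
            for f in FEATURES
        }


def default_listener_params() -> ListenerParams:
    """Preset reproducing the qualitative condition ordering.

    Auditory-only: hospital least harmful, fabric most, transparents in
    between; audiovisual: mouth-visible conditions (none, clearmask,
    communicator) gain a visual boost concentrated on place; visual-only:
    low overall, place transmitted best.  For demonstrations and end-to-end
    tests, not a claim about human listeners.
    """
    ao = {
        "none": 0.0, "hospital": -0.2, "clearmask": -0.6,
        "communicator": -0.7, "fabric": -1.0,
    }
    effects: dict[tuple[str, str], dict[str, float]] = {}
    for mask, drop in ao.items():
        effects[(mask, "AO")] = {f: drop * (1.5 if f == "place" else 1.0)
                                 for f in FEATURES}
    visual_boost = {"voicing": 0.2, "manner": 0.4, "place": 1.2}
    for mask, drop in ao.items():
        boost = visual_boost if mask in ("none", "clearmask", "communicator") else {}
        effects[(mask, "AV")] = {
            f: drop * (1.5 if f == "place" else 1.0) + boost.get(f, 0.0)
            for f in FEATURES
        }
    effects[("none", "VO")] = {"voicing": -2.2, "manner": -2.0, "place": -0.6}
    return ListenerParams(condition_effects=effects)


def simulate_listener(
    target: str,
    probabilities: dict[str, float],
    rng: np.random.Generator,
    scheme: FeatureScheme = DEFAULT_SCHEME,
) -> str:
    """One trial of the feature-channel listener.

    Each feature is transmitted independently with its probability; the
    response is uniform over consonants matching every transmitted feature
    value of the target.  When all three channels are transmitted the token
    is fully identified and the response is the target itself (under the
    feature table /h/ and /sh/ share all three values, so without this rule
    a perfect listener could never be perfect); with no channel transmitted
    the response is uniform over the full set.
    """
    transmitted = [f for f in FEATURES if rng.random() < probabilities[f]]
    if len(transmitted) == len(FEATURES):
        return target
    candidates = [
        c for c in scheme.consonants
        if all(scheme.features[f][c] == scheme.features[f][target]
               for f in transmitted)
    ]
    return candidates[int(rng.integers(len(candidates)))]


def expected_feature_transmission(
    probabilities: dict[str, float],
    scheme: FeatureScheme = DEFAULT_SCHEME,
) -> dict[str, float]:
    """Exact expectations of the listener model by exhaustive enumeration.

    Enumerates all 2^3 channel-transmission patterns for each (uniform)
    target and the uniform response draw within each candidate set, giving
    the exact expected accuracy and per-feature transmission proportions.
    """
    cons = scheme.consonants
    k = len(cons)
    totals = {"accuracy": 0.0, **{f: 0.0 for f in FEATURES}}
    for target in cons:
        for pattern in itertools.product([True, False], repeat=len(FEATURES)):
            p_pattern = 1.0
            for f, on in zip(FEATURES, pattern):
                p_pattern *= probabilities[f] if on else 1.0 - probabilities[f]
            on_feats = [f for f, on in zip(FEATURES, pattern) if on]
            if len(on_feats) == len(FEATURES):
                candidates = [target]  # full transmission identifies the token
            else:
                candidates = [
                    c for c in cons
                    if all(scheme.features[f][c] == scheme.features[f][target]
                           for f in on_feats)
                ]
            w = p_pattern / (k * len(candidates))
            for c in candidates:
                totals["accuracy"] += w * (c == target)
                for f in FEATURES:
                    totals[f] += w * (
                        scheme.features[f][c] == scheme.features[f][target]
                    )
    return totals


# ---------------------------------------------------------------------------
# Cohorts

@dataclass(frozen=True)
class CohortDesign:
    """Sampling plan of a simulated cohort.

    Defaults mirror the reference protocol: the 11 conditions, 36-trial blocks (12
    consonants x 3 tokens), two runs per condition, and 0 dB SNR for every
    group (set ``snr_db`` per group for the -10 dB adult arm).
    """

    n_per_group: dict = field(
        default_factory=lambda: {"CHL": 18, "CNH": 16, "ANH": 23}
    )
    conditions: tuple[tuple[str, str], ...] = STUDY_CONDITIONS
    trials_per_block: int = 36
    runs_per_condition: int = 2
    snr_db: dict = field(
        default_factory=lambda: {"CHL": 0.0, "CNH": 0.0, "ANH": 0.0}
    )

    def __post_init__(self) -> None:
        if self.trials_per_block % len(CONSONANTS):
            raise ValueError("trials_per_block must be a multiple of 12")
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("subject counts must be positive")
        unknown = set(self.conditions) - set(STUDY_CONDITIONS)
        if unknown:
            raise ValueError(f"conditions outside the protocol's 11: {unknown}")


_AGE_RANGES = {"CHL": (7.4, 18.9), "CNH": (7.5, 19.8), "ANH": (19.0, 50.7)}


def simulate_cohort(
    design: CohortDesign | None = None,
    params: ListenerParams | None = None,
    seed: int = 0,
    scheme: FeatureScheme = DEFAULT_SCHEME,
):
    """Full simulated trial table (one row per trial).

    Each subject gets a logit-scale random intercept, a randomized
    condition order, and per run a shuffled block of 12 consonants x
    ``trials_per_block/12`` tokens.  Returns a pandas DataFrame with the
    standard trial columns.
    """
    import pandas as pd

    design = design or CohortDesign()
    params = params or default_listener_params()
    rng = np.random.default_rng(seed)
    tokens_per_cons = design.trials_per_block // len(CONSONANTS)
    rows = []
    for group, n_subj in design.n_per_group.items():
        snr = design.snr_db.get(group, 0.0)
        for s in range(n_subj):
            subject_id = f"{group}{s + 1:02d}"
            b_i = rng.normal(0.0, params.subject_sd)
            age = rng.uniform(*_AGE_RANGES[group])
            order = rng.permutation(len(design.conditions))
            for ci in order:
                mask, modality = design.conditions[ci]
                probs = params.probabilities(mask, modality, group, b_i)
                for run in range(1, design.runs_per_condition + 1):
                    block = [(c, t + 1) for c in scheme.consonants
                             for t in range(tokens_per_cons)]
                    rng.shuffle(block)
                    for target, token in block:
                        rows.append({
                            "subject_id": subject_id,
                            "group": group,
                            "age": round(age, 1),
                            "modality": modality,
                            "mask": mask,
                            "snr_db": snr,
                            "run": run,
                            "token": token,
                            "target": target,
                            "response": simulate_listener(
                                target, probs, rng, scheme),
                        })
    return pd.DataFrame(rows)


def simulate_rau_scores(
    mask_effects_rau: dict[str, float],
    baseline_rau: float = 60.0,
    group_offsets_rau: dict[str, float] | None = None,
    n_per_group: int = 20,
    groups: tuple[str, ...] = ("CHL", "CNH", "ANH"),
    subject_sd_rau: float = 8.0,
    trials_per_cell: int = 36,
    seed: int = 0,
):
    """Score table simulated from the mixed model's own generative form.

    Each subject-by-mask cell has true score ``baseline + mask effect +
    group offset + subject intercept`` on the RAU scale; the cell's
    observed count is Binomial(``trials_per_cell``, inverse-RAU of the true
    score) and is transformed back to RAU, reproducing the sampling noise
    of a real block of trials.
    """
    import pandas as pd

    group_offsets_rau = group_offsets_rau or {g: 0.0 for g in groups}
    rng = np.random.default_rng(seed)
    from .scoring import proportion_from_rau

    rows = []
    for group in groups:
        for s in range(n_per_group):
            b_i = rng.normal(0.0, subject_sd_rau)
            for mask, effect in mask_effects_rau.items():
                true_rau = (baseline_rau + effect
                            + group_offsets_rau.get(group, 0.0) + b_i)
                p = float(np.clip(proportion_from_rau(true_rau), 1e-6, 1 - 1e-6))
                x = int(rng.binomial(trials_per_cell, p))
                rows.append({
                    "subject_id": f"{group}{s + 1:02d}",
                    "group": group,
                    "mask": mask,
                    "modality": "AO",
                    "rau": rau(x, trials_per_cell),
                    "n_correct": x,
                    "n_trials": trials_per_cell,
                })
    return pd.DataFrame(rows)
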