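"""Calibrated speech-in-noise trial assembly.

Trials follow the closed-set consonant identification protocol: a
speech-shaped noise gated on with 20-ms raised-cosine ramps at a nominal
70 dB SPL, and a CV target inserted at a fixed speech-onset time at a
requested SNR.  Levels are nominal: a :class:`CalibrationMap` declares what
dB SPL a 0-dBFS-RMS digital signal corresponds to (default 100), and all
SPL values are converted through it.  SNR is defined on the speech-span RMS
of the target relative to the noise RMS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .acoustics import (
    SpectrumEstimate,
    Waveform,
    estimate_magnitude_spectrum,
)

__all__ = [
    "CalibrationMap",
    "TrialTimeline",
    "make_speech_shaped_noise",
    "rms",
    "rms_db",
    "rms_equalize",
    "mix_trial",
]


def rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(np.asarray(x, dtype=np.float64)))))


def rms_db(x: np.ndarray) -> float:
    """RMS in dBFS (0 dBFS = unit RMS)."""
    return 20.0 * np.log10(max(rms(x), 1e-300))


@dataclass(frozen=True)
class CalibrationMap:
    """Nominal dB SPL <-> digital RMS mapping.

    ``spl_at_full_scale`` is the SPL produced by a signal with RMS 1.0
    (0 dBFS RMS).  With the default of 100, a 70 dB SPL noise sits at
    -30 dBFS RMS.
    """

    spl_at_full_scale: float = 100.0

    def spl_to_rms(self, spl_db: float) -> float:
        return 10.0 ** ((spl_db - self.spl_at_full_scale) / 20.0)

    def rms_to_spl(self, rms_value: float) -> float:
        return self.spl_at_full_scale + 20.0 * np.log10(max(rms_value, 1e-300))


@dataclass(frozen=True)
class TrialTimeline:
    """Timing of one trial, all in milliseconds.

    The video starts ``video_offset_ms`` after noise onset and must show a
    neutral face for at least ``neutral_lead_ms`` before speech-related
    movement, which constrains ``speech_onset_ms``.  The default speech
    onset (776 ms = 20-ms onset ramp + 756 ms) matches the average lead
    time of typical CV recordings in this paradigm.
    """

    speech_onset_ms: float = 776.0
    total_ms: float = 2000.0
    noise_ramp_ms: float = 20.0
    video_offset_ms: float = 186.0
    neutral_lead_ms: float = 333.0

    def __post_init__(self) -> None:
        if self.video_offset_ms + self.neutral_lead_ms > self.speech_onset_ms:
            raise ValueError(
                "timeline violates neutral-lead constraint: video offset "
                f"{self.video_offset_ms} + neutral lead {self.neutral_lead_ms} "
                f"> speech onset {self.speech_onset_ms} ms"
            )
        if 2 * self.noise_ramp_ms > self.total_ms:
            raise ValueError("ramps do not fit within the noise duration")

    @classmethod
    def for_target(cls, target: Waveform, tail_ms: float = 353.0,
                   **kwargs) -> "TrialTimeline":
        """Timeline sized so the target fits with ``tail_ms`` of trailing noise."""
        onset = kwargs.pop("speech_onset_ms", 776.0)
        total = onset + 1000.0 * len(target) / target.rate + tail_ms
        return cls(speech_onset_ms=onset, total_ms=total, **kwargs)


def make_speech_shaped_noise(
    reference: SpectrumEstimate,
    duration_s: float = 30.0,
    seed: int = 0,
    order: int = 512,
) -> Waveform:
    """Gaussian noise filtered to the long-term spectrum of the target speech.

    Seeded white noise is shaped by a linear-phase FIR whose amplitude
    response follows ``sqrt`` of the reference Welch power spectrum, then
    scaled by a single gain so that its own re-estimated spectrum sits on
    the reference (mean dB offset removed over 0.1-10 kHz).  Bit-identical
    for a fixed seed.
    """
    if duration_s <= 0:
        raise ValueError(f"duration must be positive, got {duration_s}")
    rate = reference.rate
    n = int(round(duration_s * rate))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)

    power = 10.0 ** (reference.magnitude_db / 10.0)
    gains = np.sqrt(power / power.max())
    nyq = reference.frequencies[-1]
    taps = _sig.firwin2(order + 1, reference.frequencies / nyq, gains)
    shaped = _sig.fftconvolve(white, taps, mode="full")[order // 2:][:n]

    est = estimate_magnitude_spectrum(
        Waveform(shaped, rate),
        nperseg=reference.nperseg,
        noverlap=reference.noverlap,
        window=reference.window,
    )
    band = (est.frequencies >= 100.0) & (est.frequencies <= 10000.0)
    offset_db = float(np.mean(reference.magnitude_db[band] - est.magnitude_db[band]))
    shaped *= 10.0 ** (offset_db / 20.0)
    return Waveform(shaped, rate, {"noise": (0, n)})


def rms_equalize(
    tokens: list[Waveform],
    target_rms_db: float | None = None,
    span: str = "speech",
) -> list[Waveform]:
    """Scale each token so its speech-span RMS matches a common target.

    The scale factor is computed from the annotated speech span only, so
    silent padding does not bias the level.  When ``target_rms_db`` is None
    the mean speech-span level (in dB) across tokens is used.
    """
    levels = []
    for i, tok in enumerate(tokens):
        if span not in tok.annotations:
            raise ValueError(f"token {i} has no {span!r} annotation")
        levels.append(rms_db(tok.span(span)))
    if target_rms_db is None:
        target_rms_db = float(np.mean(levels))
    out = []
    for tok, level in zip(tokens, levels):
        gain = 10.0 ** ((target_rms_db - level) / 20.0)
        out.append(Waveform(tok.samples * gain, tok.rate, dict(tok.annotations)))
    return out


def _raised_cosine_ramps(n: int, ramp_samples: int) -> np.ndarray:
    """Unit envelope with raised-cosine on/off ramps; flat (exactly 1) between."""
    env = np.ones(n)
    if ramp_samples > 0:
        t = np.arange(ramp_samples) / ramp_samples
        ramp = 0.5 * (1 - np.cos(np.pi * t))
        env[:ramp_samples] = ramp
        env[n - ramp_samples:] = ramp[::-1]
    return env


def mix_trial(
    target: Waveform,
    noise: Waveform,
    snr_db: float = 0.0,
    noise_spl: float = 70.0,
    cal: CalibrationMap | None = None,
    timeline: TrialTimeline | None = None,
    seed: int = 0,
) -> tuple[Waveform, TrialTimeline]:
    """Assemble one calibrated speech-in-noise trial.

    A contiguous noise segment is excised at a seeded random offset from the
    long noise recording, scaled to ``noise_spl`` through ``cal``, and gated
    with 20-ms raised-cosine ramps.  The target is scaled so its speech-span
    RMS equals noise RMS + ``snr_db`` and added at the timeline's speech
    onset.  The noise excision depends only on ``seed``, so the same seed at
    two SNRs yields an identical noise floor.
    """
    if target.rate != noise.rate:
        raise ValueError("target and noise sample rates differ")
    if "speech" not in target.annotations:
        raise ValueError("target has no 'speech' annotation")
    cal = cal or CalibrationMap()
    timeline = timeline or TrialTimeline.for_target(target)
    rate = target.rate
    n_total = int(round(timeline.total_ms * rate / 1000.0))
    if len(noise) < n_total:
        raise ValueError(
            f"noise ({len(noise)} samples) shorter than trial ({n_total} samples)"
        )

    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, len(noise) - n_total + 1))
    seg = noise.samples[start:start + n_total].copy()

    noise_rms_target = cal.spl_to_rms(noise_spl)
    seg *= noise_rms_target / rms(seg)
    seg *= _raised_cosine_ramps(n_total, int(round(timeline.noise_ramp_ms * rate / 1000.0)))

    speech_rms_db = cal.rms_to_spl(noise_rms_target) + snr_db  # SPL of speech span
    gain = cal.spl_to_rms(speech_rms_db) / rms(target.span("speech"))
    onset = int(round(timeline.speech_onset_ms * rate / 1000.0))
    if onset + len(target) > n_total:
        raise ValueError("target does not fit within the trial timeline")

    mix = seg
    mix[onset:onset + len(target)] += gain * target.samples
    if np.max(np.abs(mix)) > 1.0:
        raise ValueError(
            "mix clips (|sample| > 1): lower noise_spl or raise "
            "CalibrationMap.spl_at_full_scale for more digital headroom"
        )
    a, b = target.annotations["speech"]
    ann = {"noise": (0, n_total), "speech": (onset + a, onset + b)}
    if "consonant" in target.annotations:
        ca, cb = target.annotations["consonant"]
        ann["consonant"] = (onset + ca, onset + cb)
    return Waveform(mix, rate, ann), timeline
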