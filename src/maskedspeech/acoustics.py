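"""Long-term spectra, mask attenuation functions, and matching FIR filters.

The acoustic side of a simulated face mask is a frequency-dependent loss
relative to the unmasked talker.  The workflow mirrors standard practice for
measuring mask transmission loss:

1. estimate long-term magnitude spectra of paired masked / unmasked
   recordings with Welch's averaged periodogram (512-point window, 256-point
   overlap);
2. take the dB difference (unmasked minus masked) as the attenuation
   function of the mask;
3. synthesize a 129-tap linear-phase FIR filter whose magnitude response
   realizes the negative of that attenuation, so the filter can be applied
   to clean studio recordings;
4. summarize the profile as mean attenuation over 2-16 kHz and the peak
   attenuation within any standard one-third-octave band.

Spectra are stored as ``10*log10`` of the Welch power estimate.  A filter
realizing an attenuation of ``A`` dB on that scale has amplitude response
``10**(-A/20)``, so a re-estimated Welch difference of filtered vs. original
material recovers ``A`` exactly; the two dB conventions are interchangeable
for differences and this package fixes this one throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

__all__ = [
    "Waveform",
    "SpectrumEstimate",
    "AttenuationFunction",
    "MaskFilter",
    "BandSummary",
    "DEFAULT_RATE",
    "THIRD_OCTAVE_NOMINAL_HZ",
    "estimate_magnitude_spectrum",
    "attenuation_function",
    "design_mask_filter",
    "apply_filter",
    "band_mean_attenuation",
    "peak_third_octave_attenuation",
    "summarize_attenuation",
    "third_octave_bands",
]

#: Working sample rate, Hz.  Chosen so the 16 kHz one-third-octave band
#: (upper edge ~18 kHz) fits below Nyquist.
DEFAULT_RATE = 44100

_POWER_FLOOR = 1e-30  # keeps log10 finite on dead bins


@dataclass
class Waveform:
    """Mono audio in full-scale float units, with optional labelled spans.

    Annotations map a label (e.g. ``"speech"``, ``"consonant"``) to a
    ``(start, stop)`` pair in samples, half-open.
    """

    samples: np.ndarray
    rate: int = DEFAULT_RATE
    annotations: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform.samples must be 1-D (mono)")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform.samples contains non-finite values")
        n = len(self.samples)
        for label, (a, b) in self.annotations.items():
            if not (0 <= a <= b <= n):
                raise ValueError(
                    f"annotation {label!r} span ({a}, {b}) outside [0, {n}]"
                )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate

    def span(self, label: str) -> np.ndarray:
        """Samples of the annotated span ``label``."""
        try:
            a, b = self.annotations[label]
        except KeyError:
            raise KeyError(f"waveform has no annotation {label!r}") from None
        return self.samples[a:b]


@dataclass
class SpectrumEstimate:
    """One-sided averaged-periodogram magnitude spectrum, dB."""

    frequencies: np.ndarray
    magnitude_db: np.ndarray
    rate: int
    nperseg: int = 512
    noverlap: int = 256
    window: str = "hamming"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.magnitude_db = np.asarray(self.magnitude_db, dtype=np.float64)
        if self.frequencies.shape != self.magnitude_db.shape:
            raise ValueError("frequency grid and magnitude differ in length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")


@dataclass
class AttenuationFunction:
    """Frequency-indexed dB loss of a mask relative to no-mask (positive = loss)."""

    frequencies: np.ndarray
    attenuation_db: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.attenuation_db = np.asarray(self.attenuation_db, dtype=np.float64)
        if self.frequencies.shape != self.attenuation_db.shape:
            raise ValueError("frequency grid and attenuation differ in length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(self.attenuation_db)):
            raise ValueError("attenuation contains non-finite values")

    @property
    def nyquist(self) -> float:
        return float(self.frequencies[-1])

    def at(self, freqs_hz) -> np.ndarray:
        """Linear interpolation of the profile at arbitrary frequencies."""
        return np.interp(np.asarray(freqs_hz, dtype=float),
                         self.frequencies, self.attenuation_db)


@dataclass
class MaskFilter:
    """Linear-phase FIR realization of (the negative of) an attenuation profile."""

    taps: np.ndarray
    rate: int
    target: AttenuationFunction | None = None

    def __post_init__(self) -> None:
        self.taps = np.asarray(self.taps, dtype=np.float64)
        if self.taps.ndim != 1:
            raise ValueError("taps must be 1-D")
        if not np.allclose(self.taps, self.taps[::-1], atol=1e-9):
            raise ValueError("taps are not symmetric: filter is not linear phase")

    @property
    def order(self) -> int:
        return len(self.taps) - 1

    def magnitude_db(self, freqs_hz) -> np.ndarray:
        """Filter magnitude response in dB at the given frequencies."""
        freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
        _, h = _sig.freqz(self.taps, worN=freqs_hz, fs=self.rate)
        return 20.0 * np.log10(np.maximum(np.abs(h), 1e-12))


@dataclass
class BandSummary:
    """The two headline numbers of a mask profile."""

    mean_2_16k_db: float
    peak_third_octave_db: float
    peak_center_hz: float


def estimate_magnitude_spectrum(
    wave: Waveform,
    nperseg: int = 512,
    noverlap: int = 256,
    window: str = "hamming",
) -> SpectrumEstimate:
    """Welch averaged-periodogram magnitude spectrum of ``wave``, in dB.

    Defaults follow the measurement recipe: 512-point window with 256-point
    overlap, one-sided, Hamming window.  The input must be at least two
    segments long.
    """
    if len(wave) < 2 * nperseg:
        raise ValueError(
            f"signal too short for spectrum estimate: {len(wave)} samples, "
            f"need >= {2 * nperseg} (2 x nperseg)"
        )
    freqs, pxx = _sig.welch(
        wave.samples,
        fs=wave.rate,
        window=window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
    )
    mag_db = 10.0 * np.log10(np.maximum(pxx, _POWER_FLOOR))
    return SpectrumEstimate(freqs, mag_db, wave.rate, nperseg, noverlap, window)


def attenuation_function(
    masked: SpectrumEstimate,
    reference: SpectrumEstimate,
    clamp_db: float = 30.0,
    provenance: str = "",
) -> AttenuationFunction:
    """Mask attenuation: reference (no-mask) spectrum minus masked spectrum.

    Values are clamped to ``+/- clamp_db`` (default 30 dB) so bins dominated
    by measurement noise cannot drive the subsequent filter design.
    """
    if masked.frequencies.shape != reference.frequencies.shape or not np.allclose(
        masked.frequencies, reference.frequencies
    ):
        raise ValueError(
            "frequency grids differ: masked "
            f"[{masked.frequencies[0]:.1f}..{masked.frequencies[-1]:.1f}] Hz "
            f"x {len(masked.frequencies)} bins vs reference "
            f"[{reference.frequencies[0]:.1f}..{reference.frequencies[-1]:.1f}] Hz "
            f"x {len(reference.frequencies)} bins"
        )
    att = reference.magnitude_db - masked.magnitude_db
    att = np.clip(att, -clamp_db, clamp_db)
    return AttenuationFunction(reference.frequencies.copy(), att, provenance)


def design_mask_filter(att: AttenuationFunction, order: int = 128,
                       rate: int | None = None) -> MaskFilter:
    """Linear-phase FIR (frequency-sampling design) realizing ``-att``.

    ``order`` is the filter order; the filter has ``order + 1`` taps (the
    default order 128 gives 129 taps).  A zero-attenuation input yields the
    all-pass control filter: an exact unit impulse at the group-delay center.
    The order must be even (>= 8) so a type-I filter with non-zero Nyquist
    gain exists.
    """
    if order < 8:
        raise ValueError(f"filter order must be >= 8, got {order}")
    if order % 2:
        raise ValueError(
            f"filter order must be even for a type-I linear-phase design, got {order}"
        )
    if att.frequencies[0] != 0.0:
        raise ValueError("attenuation must be defined from 0 Hz")
    nyq = att.nyquist if rate is None else rate / 2.0
    if rate is not None and not np.isclose(att.nyquist, nyq):
        raise ValueError(
            f"attenuation grid ends at {att.nyquist:.1f} Hz but rate {rate} "
            f"implies Nyquist {nyq:.1f} Hz"
        )
    gains = 10.0 ** (-att.attenuation_db / 20.0)
    taps = _sig.firwin2(order + 1, att.frequencies / nyq, gains)
    return MaskFilter(taps, rate=int(round(2 * nyq)), target=att)


def apply_filter(wave: Waveform, filt: MaskFilter) -> Waveform:
    """Filter ``wave``, compensating the ``order/2`` group delay.

    Output has the same length as the input: the linear-phase delay is
    removed by discarding the first ``order/2`` convolution samples, and the
    tail is zero-padded.  Annotations therefore stay aligned.
    """
    if wave.rate != filt.rate:
        raise ValueError(
            f"sample-rate mismatch: waveform {wave.rate} Hz, filter designed "
            f"for {filt.rate} Hz"
        )
    full = _sig.fftconvolve(wave.samples, filt.taps, mode="full")
    delay = filt.order // 2
    out = full[delay:delay + len(wave)]
    if len(out) < len(wave):  # shorter than one filter length
        out = np.pad(out, (0, len(wave) - len(out)))
    return Waveform(out, wave.rate, dict(wave.annotations))


def band_mean_attenuation(att: AttenuationFunction, f_lo: float, f_hi: float) -> float:
    """Unweighted mean attenuation over grid bins in ``[f_lo, f_hi]`` (inclusive)."""
    if not (0 <= f_lo < f_hi <= att.nyquist):
        raise ValueError(
            f"invalid band [{f_lo}, {f_hi}] Hz for grid ending at "
            f"{att.nyquist:.1f} Hz"
        )
    sel = (att.frequencies >= f_lo) & (att.frequencies <= f_hi)
    if not np.any(sel):
        raise ValueError(f"band [{f_lo}, {f_hi}] Hz contains no frequency bins")
    return float(np.mean(att.attenuation_db[sel]))


#: Exact base-2 one-third-octave centers 1000*2^(n/3) for n = -10..12 and
#: their conventional nominal labels.
_N_RANGE = np.arange(-10, 13)
_EXACT_CENTERS = 1000.0 * 2.0 ** (_N_RANGE / 3.0)
THIRD_OCTAVE_NOMINAL_HZ = np.array(
    [100, 125, 160, 200, 250, 315, 400, 500, 630, 800, 1000, 1250, 1600,
     2000, 2500, 3150, 4000, 5000, 6300, 8000, 10000, 12500, 16000],
    dtype=float,
)


def third_octave_bands(nyquist: float) -> list[tuple[float, float, float]]:
    """Standard one-third-octave bands that fit below ``nyquist``.

    Returns ``(nominal_center, f_lo, f_hi)`` triples with edges at
    ``center * 2**(+/-1/6)`` around the exact base-2 center.
    """
    bands = []
    for nominal, exact in zip(THIRD_OCTAVE_NOMINAL_HZ, _EXACT_CENTERS):
        lo, hi = exact * 2 ** (-1 / 6), exact * 2 ** (1 / 6)
        if hi <= nyquist:
            bands.append((float(nominal), lo, hi))
    return bands


def peak_third_octave_attenuation(
    att: AttenuationFunction, n_interp: int = 64
) -> tuple[float, float]:
    """Largest one-third-octave-band mean attenuation and its nominal center.

    Band means use linear interpolation of the profile on a fine log-spaced
    in-band grid (the Welch grid is too coarse to land bins in the lowest
    bands).  Ties go to the lowest-frequency band.
    """
    if att.frequencies[0] > 100.0:
        raise ValueError("attenuation must cover at least 0.1 kHz upward")
    bands = third_octave_bands(att.nyquist)
    if not bands:
        raise ValueError("no one-third-octave band fits below Nyquist")
    best_db, best_center = -np.inf, None
    for nominal, lo, hi in bands:
        grid = np.geomspace(lo, hi, n_interp)
        mean_db = float(np.mean(att.at(grid)))
        if mean_db > best_db + 1e-12:
            best_db, best_center = mean_db, nominal
    return best_db, best_center


def summarize_attenuation(att: AttenuationFunction) -> BandSummary:
    """The 2-16 kHz mean and peak one-third-octave attenuation of a profile."""
    peak_db, center = peak_third_octave_attenuation(att)
    return BandSummary(
        mean_2_16k_db=band_mean_attenuation(att, 2000.0, 16000.0),
        peak_third_octave_db=peak_db,
        peak_center_hz=center,
    )
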