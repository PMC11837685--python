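"""Detrending, Gaussian resampling and Morse-wavelet spectrograms.

Each sway channel is mean-subtracted, resampled to 50 Hz with a Gaussian
moving-average kernel (sigma = 1/60 s), and decomposed with a continuous
wavelet transform using generalized Morse wavelets (shape gamma = 3,
36 voices per octave, frequency range [0.12, 15] Hz).  A 30 s trial
yields 1500 time points, hence a 250 x 1500 energy matrix that is cut
into six contiguous 250 x 250 spectrogram image samples.

The Morse wavelet is defined in the frequency domain as
``psi(w) ~ w**beta * exp(-w**gamma)`` for ``w > 0`` (analytic), with peak
angular frequency ``(beta/gamma)**(1/gamma)``.  The order beta is not a
measurement constraint here; the default beta = 20 gives time-bandwidth
product ``beta * gamma = 60``, a common choice for gamma = 3 analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

__all__ = [
    "ResampledSignal",
    "Spectrogram",
    "SpectrogramSample",
    "detrend",
    "gaussian_resample",
    "morse_freq_axis",
    "morse_cwt",
    "segment_spectrogram",
]

PIPELINE_RATE = 50.0  # Hz, the analysis rate all spectrogram axes assume


@dataclass
class ResampledSignal:
    """Zero-mean displacement signal on a uniform grid."""

    values: np.ndarray
    rate: float

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class Spectrogram:
    """Wavelet energy as a function of time and frequency.

    ``energy`` has shape (n_freq, n_time); ``freqs`` is descending
    (highest band first, matching image row order top-to-bottom).
    """

    energy: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.energy = np.asarray(self.energy)
        if self.energy.ndim != 2:
            raise ValueError("energy must be 2-D (n_freq, n_time)")
        if self.energy.shape != (len(self.freqs), len(self.times)):
            raise ValueError("energy shape must match freqs x times axes")
        if np.any(self.energy < 0):
            raise ValueError("energy must be nonnegative")


@dataclass
class SpectrogramSample:
    """One contiguous time segment of a trial spectrogram, used as a
    grayscale image sample (250 x 250 px in the full pipeline)."""

    pixels: np.ndarray
    freqs: np.ndarray
    segment_index: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if np.any(self.pixels < 0):
            raise ValueError("pixels must be nonnegative")


def detrend(x) -> np.ndarray:
    """Subtract the mean."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot detrend an empty signal")
    return x - x.mean()


def gaussian_resample(x, t_in, out_rate=PIPELINE_RATE, sigma=1.0 / 60.0):
    """Resample onto a uniform grid with a Gaussian moving-average kernel.

    The output at time tau is ``sum_i w_i x_i / sum_i w_i`` with
    ``w_i = exp(-(t_i - tau)^2 / (2 sigma^2))``, evaluated over a symmetric
    +-5 sigma window.  The output grid is ``t_in[0] + k / out_rate`` with
    ``round(duration * out_rate)`` samples, so a 30 s trial at any input
    rate yields 1500 points at 50 Hz.
    """
    x = np.asarray(x, dtype=float)
    t_in = np.asarray(t_in, dtype=float)
    if len(x) != len(t_in):
        raise ValueError("x and t_in must have equal length")
    if len(t_in) < 2 or np.any(np.diff(t_in) <= 0):
        raise ValueError("t_in must be strictly increasing with >= 2 samples")
    dt = np.median(np.diff(t_in))
    duration = t_in[-1] - t_in[0] + dt
    n_out = int(round(duration * out_rate))
    if n_out < 1:
        raise ValueError("input shorter than one output sample")
    tau = t_in[0] + np.arange(n_out) / out_rate
    half = 5.0 * sigma
    lo = np.searchsorted(t_in, tau - half, side="left")
    hi = np.searchsorted(t_in, tau + half, side="right")
    m = int((hi - lo).max())
    offs = lo[:, None] + np.arange(m)[None, :]
    mask = offs < hi[:, None]
    offs = np.clip(offs, 0, len(t_in) - 1)
    w = np.exp(-((t_in[offs] - tau[:, None]) ** 2) / (2.0 * sigma**2)) * mask
    values = (w * x[offs]).sum(axis=1) / w.sum(axis=1)
    return ResampledSignal(values=values, rate=float(out_rate))


def morse_freq_axis(n_freqs=250, f_max=15.0, voices=36) -> np.ndarray:
    """Geometric frequency grid: ``n_freqs`` bands descending from
    ``f_max`` in steps of ``2**(-1/voices)``.

    With the defaults the 250th band sits at ~0.122 Hz, realising the
    [0.12, 15] Hz analysis range with exactly 250 voices-per-octave bands.
    """
    return f_max * 2.0 ** (-np.arange(n_freqs) / voices)


def _morse_filters(freqs_hz, nfft, rate, gamma, beta):
    """Frequency-domain Morse wavelets, unit peak amplitude, analytic."""
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, 1.0 / rate)
    peak = (beta / gamma) ** (1.0 / gamma)
    filters = np.zeros((len(freqs_hz), nfft))
    pos = omega > 0
    for i, fc in enumerate(freqs_hz):
        scale = peak / (2.0 * np.pi * fc)
        w = scale * omega[pos]
        filters[i, pos] = 2.0 * np.exp(
            beta * np.log(w / peak) - w**gamma + peak**gamma
        )
    return filters


def morse_cwt(signal, gamma=3.0, beta=20.0, voices=36, f_range=(0.12, 15.0),
              n_freqs=250, energy="power", expected_rate=PIPELINE_RATE,
              meta=None) -> Spectrogram:
    """Continuous wavelet transform with generalized Morse wavelets.

    ``signal`` is a :class:`ResampledSignal`; its rate must equal
    ``expected_rate`` (the frequency axis would silently mis-scale
    otherwise).  The signal is reflection-padded on both sides, filtered
    in the frequency domain, and cropped back, giving an
    ``(n_freqs, n)`` energy matrix.  ``energy`` is the squared magnitude
    of the wavelet coefficients (``"power"``, default) or the magnitude
    (``"magnitude"``).

    The frequency grid descends geometrically from ``f_range[1]`` at 36
    voices per octave and keeps the first ``n_freqs`` bands; the printed
    range and the band count disagree by about one voice, so the count
    wins (the lowest band lands at ~0.122 Hz).
    """
    if not isinstance(signal, ResampledSignal):
        raise TypeError("morse_cwt expects a ResampledSignal")
    if expected_rate is not None and signal.rate != expected_rate:
        raise ValueError(
            f"signal rate {signal.rate} Hz != expected {expected_rate} Hz; "
            "the spectrogram frequency axis would mis-scale"
        )
    if energy not in ("power", "magnitude"):
        raise ValueError("energy must be 'power' or 'magnitude'")
    f_max = f_range[1]
    if not 0 < f_max < signal.rate / 2.0:
        raise ValueError("f_range must lie within (0, Nyquist)")
    x = np.asarray(signal.values, dtype=float)
    n = len(x)
    freqs = morse_freq_axis(n_freqs=n_freqs, f_max=f_max, voices=voices)
    xp = np.concatenate([x[::-1], x, x[::-1]])
    nfft = len(xp)
    filters = _morse_filters(freqs, nfft, signal.rate, gamma, beta)
    spec = sfft.fft(xp)
    coeffs = sfft.ifft(spec[None, :] * filters, axis=1)[:, n : 2 * n]
    mag2 = coeffs.real**2 + coeffs.imag**2
    e = mag2 if energy == "power" else np.sqrt(mag2)
    times = np.arange(n) / signal.rate
    return Spectrogram(energy=e, freqs=freqs, times=times, meta=dict(meta or {}))


def segment_spectrogram(spec: Spectrogram, n_segments=6):
    """Cut a trial spectrogram into contiguous, non-overlapping column
    blocks; concatenating the segments reconstructs the input exactly."""
    n_time = spec.energy.shape[1]
    if n_segments < 1 or n_time % n_segments:
        raise ValueError(
            f"{n_time} time points not divisible into {n_segments} segments"
        )
    width = n_time // n_segments
    out = []
    for s in range(n_segments):
        block = spec.energy[:, s * width : (s + 1) * width]
        out.append(SpectrogramSample(
            pixels=block.copy(), freqs=spec.freqs, segment_index=s,
            meta={**spec.meta, "segment_index": s},
        ))
    return out
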