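"""Continuous wavelet transform with generalized Morse wavelets.

Each segment channel is transformed with an analytic generalized Morse
wavelet (GMW), the standard two-parameter analytic family

    Psi(omega) ∝ omega**beta * exp(-omega**gamma),   omega > 0

parameterized by the symmetry parameter gamma and the time-bandwidth product
P^2 = beta * gamma.  The defaults gamma = 3, P^2 = 60 (so beta = 20) give a
near-symmetric, tightly localized wavelet.  The transform is evaluated in
the frequency domain over a geometric scale ladder with a fixed number of
voices per octave, and the magnitude is rendered as a fixed-size 8-bit gray
image for downstream patch featurization.

Scale limits are chosen automatically: the smallest scale puts the wavelet
peak at Nyquist; the largest is capped so that roughly two wavelet
standard deviations (2 * a * sqrt(beta * gamma) samples) fit inside the
signal window.  The convolution is circular (no padding, no
cone-of-influence masking), so circularly shifting the input shifts every
scalogram row exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

__all__ = [
    "MorseParams",
    "Scalogram",
    "TFImage",
    "morse_wavelet_freq",
    "morse_peak_omega",
    "cwt_morse",
    "render_tf_image",
    "scalogram_image",
]


@dataclass(frozen=True)
class MorseParams:
    """Generalized Morse wavelet parameters.

    ``beta`` is always derived as time_bandwidth / gamma; the admissibility
    condition beta > 1 requires time_bandwidth > gamma.
    """

    gamma: float = 3.0
    time_bandwidth: float = 60.0
    voices_per_octave: int = 10

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if not self.time_bandwidth > self.gamma:
            raise ValueError(
                f"time_bandwidth ({self.time_bandwidth}) must exceed gamma "
                f"({self.gamma}) for an admissible analytic wavelet"
            )
        if self.voices_per_octave < 1:
            raise ValueError("voices_per_octave must be >= 1")

    @property
    def beta(self) -> float:
        return self.time_bandwidth / self.gamma

    @property
    def peak_omega(self) -> float:
        """Peak angular frequency (rad/sample at unit scale)."""
        return morse_peak_omega(self.beta, self.gamma)


def morse_peak_omega(beta: float, gamma: float) -> float:
    """Angular frequency where the GMW magnitude peaks: (beta/gamma)^(1/gamma)."""
    return (beta / gamma) ** (1.0 / gamma)


def morse_wavelet_freq(beta: float, gamma: float, omega: np.ndarray) -> np.ndarray:
    """Frequency-domain GMW, peak-normalized to 2, zero for omega <= 0.

    Evaluated in the log domain for stability at large beta:
    Psi(omega) = 2 * exp(beta*ln(omega) - omega^gamma - (beta*ln(wp) - wp^gamma)).
    """
    if not (beta > 0 and gamma > 0):
        raise ValueError("beta and gamma must be positive")
    omega = np.asarray(omega, dtype=np.float64)
    wp = morse_peak_omega(beta, gamma)
    log_peak = beta * np.log(wp) - wp**gamma
    out = np.zeros_like(omega)
    pos = omega > 0
    w = omega[pos]
    out[pos] = 2.0 * np.exp(beta * np.log(w) - w**gamma - log_peak)
    return out


@dataclass
class Scalogram:
    """CWT magnitude over (scale, time), high frequencies in the top rows."""

    magnitude: np.ndarray
    freqs: np.ndarray  # Hz per row, strictly decreasing
    scale_list: np.ndarray  # samples, strictly increasing, geometric ladder

    def __post_init__(self) -> None:
        if len(self.freqs) != len(self.scale_list) or len(self.freqs) != self.magnitude.shape[0]:
            raise ValueError("freqs, scale_list and magnitude rows must align")


@dataclass
class TFImage:
    """Fixed-size square 8-bit gray rendering of a scalogram."""

    pixels: np.ndarray
    source: tuple[str, int] = ("", 0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"TFImage must be square, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError("TFImage pixels must be uint8")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def _scale_ladder(n_samples: int, params: MorseParams) -> np.ndarray:
    wp = params.peak_omega
    a_min = wp / np.pi  # wavelet peak at Nyquist
    # largest scale: two time-domain standard deviations (~a*sqrt(beta*gamma)
    # samples each) must fit in the window
    a_max = n_samples / (2.0 * np.sqrt(params.beta * params.gamma))
    if a_max <= a_min:
        raise ValueError(
            f"signal of {n_samples} samples is too short for any valid scale "
            f"with time_bandwidth={params.time_bandwidth}"
        )
    ratio = 2.0 ** (1.0 / params.voices_per_octave)
    n_scales = int(np.floor(np.log(a_max / a_min) / np.log(ratio))) + 1
    return a_min * ratio ** np.arange(n_scales)


def cwt_morse(x: np.ndarray, fs: float, params: MorseParams | None = None) -> Scalogram:
    """FFT-based CWT of a real signal with an analytic GMW.

    X(a, b) is evaluated as the inverse FFT of fft(x) * Psi(a * omega) for
    each scale a on the geometric ladder; rows are ordered high frequency
    first.  Row frequencies are the wavelet peak mapping
    f = fs * omega_p / (2 * pi * a).
    """
    params = params or MorseParams()
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("cwt_morse expects a 1-D signal")
    n = x.size
    if n < 32:
        raise ValueError(f"signal too short for CWT: {n} samples (need >= 32)")
    if not np.all(np.isfinite(x)):
        raise ValueError("input signal contains NaN or Inf")
    scales = _scale_ladder(n, params)
    omega = 2.0 * np.pi * np.fft.fftfreq(n)  # rad/sample, signed
    xh = np.fft.fft(x)
    mag = np.empty((scales.size, n), dtype=np.float64)
    for i, a in enumerate(scales):
        psi = morse_wavelet_freq(params.beta, params.gamma, a * omega)
        mag[i] = np.abs(np.fft.ifft(xh * psi))
    freqs = fs * params.peak_omega / (2.0 * np.pi * scales)
    # smallest scale = highest frequency already first; keep descending freqs
    return Scalogram(magnitude=mag, freqs=freqs, scale_list=scales)


def render_tf_image(
    s: Scalogram, size: int = 225, source: tuple[str, int] = ("", 0)
) -> TFImage:
    """Min-max normalize the magnitude to [0, 255] and resample to size x size.

    Bilinear interpolation, rounding half-up.  A constant magnitude matrix
    (max == min, e.g. an all-zero signal) maps to an all-zero image.
    """
    mag = np.asarray(s.magnitude, dtype=np.float64)
    if mag.size == 0:
        raise ValueError("empty scalogram")
    lo, hi = mag.min(), mag.max()
    if hi > lo:
        norm = (mag - lo) / (hi - lo)
    else:
        norm = np.zeros_like(mag)
    if norm.shape != (size, size):
        norm = resize(
            norm, (size, size), order=1, mode="edge", anti_aliasing=False,
            preserve_range=True,
        )
    pixels = np.floor(norm * 255.0 + 0.5).clip(0, 255).astype(np.uint8)
    return TFImage(pixels=pixels, source=source)


def scalogram_image(
    x: np.ndarray,
    fs: float,
    params: MorseParams | None = None,
    size: int = 225,
    source: tuple[str, int] = ("", 0),
) -> TFImage:
    """Convenience: CWT then gray rendering in one call."""
    return render_tf_image(cwt_morse(x, fs, params), size=size, source=source)
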